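"""The nine feature-integration strategies: per-position channel matrices
built from raw kinetics, baseline-predicted kinetics and one-hot sequence.

Strategies 1-6 use baseline-referenced features — the element-wise difference
(raw - predicted) and/or ratio (raw / predicted) for both IPD and PW —
optionally with the one-hot sequence.  Strategy 7 is the ablation without any
predicted signal (raw + sequence); 8 and 9 concatenate raw and predicted
directly without subtraction or division.

Channel counts (IPD+PW pairs contribute 2 channels each, sequence 4):

    ID  composition                 channels
    1   diff                        2
    2   ratio                       2
    3   diff + ratio                4
    4   diff + seq                  6
    5   ratio + seq                 6
    6   diff + ratio + seq          8
    7   raw + seq                   6
    8   raw + pred                  4
    9   raw + pred + seq            8
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baseline_regressor import encode_onehot
from .windows import SampleWindow, KIN_FLANK

WINDOW = 2 * KIN_FLANK + 1

__all__ = [
    "StrategyID", "FeatureBlock", "STRATEGY_COMPONENTS",
    "kinetics_difference", "kinetics_ratio", "build_features",
    "channel_count",
]

# strategy id -> ordered component list
STRATEGY_COMPONENTS: dict[int, tuple[str, ...]] = {
    1: ("diff",),
    2: ("ratio",),
    3: ("diff", "ratio"),
    4: ("diff", "seq"),
    5: ("ratio", "seq"),
    6: ("diff", "ratio", "seq"),
    7: ("raw", "seq"),
    8: ("raw", "pred"),
    9: ("raw", "pred", "seq"),
}

# component -> (channel names, modality group for late fusion)
_COMPONENT_CHANNELS: dict[str, tuple[tuple[str, ...], str]] = {
    "diff": (("diff_ipd", "diff_pw"), "baseline"),
    "ratio": (("ratio_ipd", "ratio_pw"), "baseline"),
    "raw": (("raw_ipd", "raw_pw"), "raw"),
    "pred": (("pred_ipd", "pred_pw"), "baseline"),
    "seq": (("A", "C", "G", "T"), "seq"),
}


@dataclass(frozen=True)
class StrategyID:
    """One row of the strategy table, with the flags it implies."""

    id: int

    def __post_init__(self) -> None:
        if self.id not in STRATEGY_COMPONENTS:
            raise ValueError(f"strategy id must be 1..9, got {self.id}")

    @property
    def components(self) -> tuple[str, ...]:
        return STRATEGY_COMPONENTS[self.id]

    @property
    def uses_difference(self) -> bool:
        return "diff" in self.components

    @property
    def uses_ratio(self) -> bool:
        return "ratio" in self.components

    @property
    def uses_sequence(self) -> bool:
        return "seq" in self.components

    @property
    def uses_raw_concat(self) -> bool:
        return "raw" in self.components

    @property
    def needs_baseline(self) -> bool:
        """True when the strategy requires the baseline regressor's output."""
        return any(c in ("diff", "ratio", "pred") for c in self.components)


def channel_count(strategy: StrategyID | int) -> int:
    sid = strategy if isinstance(strategy, StrategyID) else StrategyID(strategy)
    return sum(len(_COMPONENT_CHANNELS[c][0]) for c in sid.components)


@dataclass
class FeatureBlock:
    """21 x C per-position feature matrix plus its channel layout.

    ``layout`` names each channel; ``groups`` tags each channel with its
    modality (raw / baseline / seq) for the late-fusion architecture.
    """

    matrix: np.ndarray
    layout: tuple[str, ...]
    groups: tuple[str, ...]
    strategy: int

    def __post_init__(self) -> None:
        if self.matrix.shape != (WINDOW, len(self.layout)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with layout")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")

    def columns(self, group: str) -> np.ndarray:
        idx = [i for i, g in enumerate(self.groups) if g == group]
        return self.matrix[:, idx]


def kinetics_difference(raw: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Element-wise raw - predicted (the baseline-referenced difference)."""
    raw = np.asarray(raw, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if raw.shape != predicted.shape:
        raise ValueError("raw/predicted length mismatch")
    return raw - predicted


def kinetics_ratio(raw: np.ndarray, predicted: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Element-wise raw / max(predicted, eps).

    Under mean-scale normalization the predicted signal hovers near 1; the
    clamp only guards pathological near-zero predictions.
    """
    raw = np.asarray(raw, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if raw.shape != predicted.shape:
        raise ValueError("raw/predicted length mismatch")
    out = raw / np.maximum(predicted, eps)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite kinetics ratio")
    return out


def build_features(window: SampleWindow,
                   predicted_ipd: np.ndarray | None,
                   predicted_pw: np.ndarray | None,
                   strategy: StrategyID | int,
                   eps: float = 1e-3) -> FeatureBlock:
    """Assemble the 21 x C feature matrix for one sample window.

    Strategies needing the baseline (1-6, 8, 9) require predicted vectors;
    strategy 7 works without them.
    """
    sid = strategy if isinstance(strategy, StrategyID) else StrategyID(strategy)
    if sid.needs_baseline and (predicted_ipd is None or predicted_pw is None):
        raise ValueError(f"strategy {sid.id} requires baseline predictions")
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: list[str] = []
    center = window.seq41[KIN_FLANK: KIN_FLANK + WINDOW]
    for comp in sid.components:
        ch_names, group = _COMPONENT_CHANNELS[comp]
        if comp == "diff":
            block = np.stack([kinetics_difference(window.kin21_ipd, predicted_ipd),
                              kinetics_difference(window.kin21_pw, predicted_pw)], axis=1)
        elif comp == "ratio":
            block = np.stack([kinetics_ratio(window.kin21_ipd, predicted_ipd, eps),
                              kinetics_ratio(window.kin21_pw, predicted_pw, eps)], axis=1)
        elif comp == "raw":
            block = np.stack([window.kin21_ipd, window.kin21_pw], axis=1)
        elif comp == "pred":
            block = np.stack([np.asarray(predicted_ipd, dtype=float),
                              np.asarray(predicted_pw, dtype=float)], axis=1)
        else:  # seq
            block = encode_onehot(center)
        cols.append(block)
        names.extend(ch_names)
        groups.extend([group] * len(ch_names))
    return FeatureBlock(np.concatenate(cols, axis=1), tuple(names), tuple(groups), sid.id)
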