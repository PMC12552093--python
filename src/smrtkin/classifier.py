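"""Binary methylation classifier over per-position feature blocks.

Two architectures share one training recipe:

* ``early_concat`` — a single BiGRU over the full 21 x C feature matrix, its
  final bidirectional state fed to a fully connected 2-logit softmax head.
* ``late_fusion`` — one BiGRU branch per feature modality (raw kinetics,
  baseline-referenced kinetics, sequence); the branches' final states are
  concatenated before the head.  Preferred when predicted baselines are noisy
  (CCS-style data), since each modality keeps its own representation.

Training uses focal loss (focusing parameter gamma, default 2) composed with
label smoothing (default 0.1), Adam at lr 1e-3 with step decay (x0.5 every 10
epochs), and F1-maximizing threshold calibration on a validation split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .baseline_regressor import BaselineModel, predict_baseline_batch
from .features import StrategyID, build_features, channel_count
from .windows import SampleWindow

__all__ = [
    "ClassifierConfig", "TrainedClassifier",
    "focal_loss", "smooth_labels", "calibrate_threshold",
    "train_classifier", "predict", "feature_tensor",
]

LABEL_TO_INT = {"unmethylated": 0, "methylated": 1}


@dataclass
class ClassifierConfig:
    architecture: str = "early_concat"    # or "late_fusion"
    gru_hidden: int = 32
    dropout: float = 0.2
    lr: float = 1e-3
    step_size: int = 10                   # epochs between learning-rate halvings
    gamma_lr: float = 0.5
    focal_gamma: float = 2.0
    label_smoothing: float = 0.1
    epochs: int = 30
    batch: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("early_concat", "late_fusion"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not (0.0 <= self.label_smoothing < 0.5):
            raise ValueError("label_smoothing must lie in [0, 0.5)")
        if not (0.0 < self.gamma_lr <= 1.0):
            raise ValueError("gamma_lr must lie in (0, 1]")
        if self.lr <= 0 or self.epochs < 1:
            raise ValueError("lr must be > 0 and epochs >= 1")


def focal_loss(p_true: np.ndarray | float, gamma: float = 2.0,
               clamp: float = 1e-7) -> float:
    """Focal loss -(1 - p_t)^gamma * log(p_t), batch-mean reduced.

    ``p_true`` is the predicted probability of the true class (p if the label
    is methylated, 1-p otherwise), clamped at ``clamp`` before the log.
    """
    p = np.atleast_1d(np.asarray(p_true, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, clamp, 1.0)
    return float(np.mean(-((1.0 - p) ** gamma) * np.log(p)))


def smooth_labels(labels: np.ndarray | Sequence[int], factor: float = 0.1) -> np.ndarray:
    """Hard 0/1 labels -> two-class soft targets by uniform smoothing.

    The true class receives 1 - factor + factor/2, the other factor/2, so a
    label of 1 at factor 0.1 becomes (0.05, 0.95).
    """
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be 0/1")
    if not (0.0 <= factor < 0.5):
        raise ValueError("factor must lie in [0, 0.5)")
    targets = np.full((len(labels), 2), factor / 2.0)
    targets[np.arange(len(labels)), labels] = 1.0 - factor / 2.0
    return targets


def calibrate_threshold(scores: np.ndarray, labels: np.ndarray,
                        ) -> tuple[float, float]:
    """F1-maximizing decision threshold on a validation set.

    Candidates are midpoints of consecutive sorted unique scores plus the
    {0, 1} boundaries; calls are ``score >= threshold``; ties resolve to the
    lowest threshold.  Degenerate all-equal scores return 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    if uniq.size == 1:
        warnings.warn("degenerate scores: all equal; threshold defaults to 0.5")
        preds = scores >= 0.5
        return 0.5, _f1(preds, labels)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    best_thr, best_f1 = candidates[0], -1.0
    for thr in candidates:
        f1 = _f1(scores >= thr, labels)
        if f1 > best_f1 + 1e-12:
            best_thr, best_f1 = thr, f1
    return float(best_thr), float(best_f1)


def _f1(calls: np.ndarray, labels: np.ndarray) -> float:
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


# --------------------------------------------------------------------------
# network


class _Net:
    """Shared forward/backward plumbing for both architectures."""

    def __init__(self, cfg: ClassifierConfig, groups: tuple[str, ...]):
        self.cfg = cfg
        self.groups = groups
        rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(21,)))
        if cfg.architecture == "early_concat":
            self.branch_cols = {"all": list(range(len(groups)))}
        else:
            order = []
            for g in groups:
                if g not in order:
                    order.append(g)
            self.branch_cols = {g: [i for i, gg in enumerate(groups) if gg == g]
                                for g in order}
        self.branches = {name: _nn.BiGRU(len(cols), cfg.gru_hidden, rng)
                         for name, cols in self.branch_cols.items()}
        fused = sum(b.output_dim for b in self.branches.values())
        self.head = _nn.Dense(fused, 2, rng)
        self._drop_mask: np.ndarray | None = None

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for name, b in self.branches.items():
            out.update({f"br.{name}.{k}": v for k, v in b.params.items()})
        out.update({f"head.{k}": v for k, v in self.head.params.items()})
        return out

    def set_parameter(self, name: str, value: np.ndarray) -> None:
        if name.startswith("head."):
            self.head.params[name[5:]] = value
        else:
            _, branch, key = name.split(".", 2)
            self.branches[branch].set_param(key, value)

    def forward(self, x: np.ndarray, dropout_rng: np.random.Generator | None = None,
                ) -> np.ndarray:
        hs = [self.branches[name].forward(x[:, :, cols])
              for name, cols in self.branch_cols.items()]
        h = np.concatenate(hs, axis=1)
        p = self.cfg.dropout
        if dropout_rng is not None and p > 0:
            self._drop_mask = (dropout_rng.random(h.shape) >= p) / (1.0 - p)
            h = h * self._drop_mask
        else:
            self._drop_mask = None
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        dh, g_head = self.head.backward(dlogits)
        if self._drop_mask is not None:
            dh = dh * self._drop_mask
        grads = {f"head.{k}": v for k, v in g_head.items()}
        start = 0
        for name, b in self.branches.items():
            width = b.output_dim
            _, g = b.backward(dh[:, start:start + width])
            grads.update({f"br.{name}.{k}": v for k, v in g.items()})
            start += width
        return grads


class TrainedClassifier:
    """Frozen classifier bundling weights, strategy, and calibrated threshold."""

    def __init__(self, net: _Net, config: ClassifierConfig, strategy: int,
                 groups: tuple[str, ...], threshold: float, val_f1: float):
        self.net = net
        self.config = config
        self.strategy = strategy
        self.groups = groups
        self.threshold = threshold
        self.val_f1 = val_f1
        self.loss_trace: list[float] = []

    def scores(self, feats: np.ndarray, batch: int = 4096) -> np.ndarray:
        """Probability of the methylated class per sample; deterministic."""
        out = []
        for start in range(0, len(feats), batch):
            logits = self.net.forward(feats[start:start + batch])
            out.append(_nn.softmax(logits)[:, 1])
        return np.concatenate(out) if out else np.zeros(0)

    def save(self, path: str | Path, baseline_fingerprint: str = "") -> None:
        meta = {"config": asdict(self.config), "strategy": self.strategy,
                "groups": list(self.groups), "threshold": self.threshold,
                "val_f1": self.val_f1, "baseline_fingerprint": baseline_fingerprint}
        params = {k.replace(".", "__"): v for k, v in self.net.parameters().items()}
        np.savez(Path(path), __meta__=json.dumps(meta), **params)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = ClassifierConfig(**meta["config"])
            net = _Net(cfg, tuple(meta["groups"]))
            for k in data.files:
                if k != "__meta__":
                    net.set_parameter(k.replace("__", "."), data[k])
        return cls(net, cfg, meta["strategy"], tuple(meta["groups"]),
                   meta["threshold"], meta["val_f1"])


def feature_tensor(windows: Sequence[SampleWindow], strategy: StrategyID | int,
                   baseline: BaselineModel | None,
                   eps: float = 1e-3) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Stacked (n, 21, C) features, 0/1 labels and the channel groups.

    Baseline predictions (when the strategy needs them) are computed in one
    batched pass through the frozen regressor.
    """
    if not windows:
        raise ValueError("no sample windows to featurize")
    sid = strategy if isinstance(strategy, StrategyID) else StrategyID(strategy)
    if sid.needs_baseline:
        if baseline is None:
            raise ValueError(f"strategy {sid.id} requires a baseline model")
        preds = predict_baseline_batch(baseline, [w.seq41 for w in windows])
    blocks, labels = [], []
    groups: tuple[str, ...] | None = None
    for j, w in enumerate(windows):
        pi, pp = (preds[j, :, 0], preds[j, :, 1]) if sid.needs_baseline else (None, None)
        fb = build_features(w, pi, pp, sid, eps=eps)
        blocks.append(fb.matrix)
        groups = fb.groups
        labels.append(LABEL_TO_INT.get(w.label, -1))
    feats = np.stack(blocks)
    assert feats.shape[2] == channel_count(sid)
    return feats, np.array(labels), groups


def train_classifier(train_windows: Sequence[SampleWindow],
                     val_windows: Sequence[SampleWindow],
                     strategy: StrategyID | int,
                     baseline: BaselineModel | None,
                     cfg: ClassifierConfig) -> TrainedClassifier:
    """Train, then calibrate the decision threshold on the validation set."""
    Xtr, ytr, groups = feature_tensor(train_windows, strategy, baseline)
    Xva, yva, _ = feature_tensor(val_windows, strategy, baseline)
    for name, y in (("train", ytr), ("validation", yva)):
        if len(np.unique(y[y >= 0])) < 2:
            raise ValueError(f"{name} set must contain both classes")
    targets = smooth_labels(ytr, cfg.label_smoothing)
    sid = strategy if isinstance(strategy, StrategyID) else StrategyID(strategy)
    net = _Net(cfg, groups)
    opt = _nn.Adam(net.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(22,)))
    drop_rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(23,)))
    trace = []
    n = len(Xtr)
    for epoch in range(cfg.epochs):
        lr = _nn.step_lr(cfg.lr, epoch, cfg.step_size, cfg.gamma_lr)
        epoch_loss, n_batches = 0.0, 0
        for idx in _nn.iter_minibatches(n, cfg.batch, rng):
            logits = net.forward(Xtr[idx], dropout_rng=drop_rng)
            loss, dlogits = _nn.focal_smoothed_loss_and_grad(
                logits, targets[idx], gamma=cfg.focal_gamma)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            grads = net.backward(dlogits)
            params = net.parameters()
            opt.step(params, grads, lr=lr)
            for name, val in params.items():
                net.set_parameter(name, val)
            epoch_loss += loss
            n_batches += 1
        trace.append(epoch_loss / max(n_batches, 1))
    clf = TrainedClassifier(net, cfg, sid.id, groups, threshold=0.5, val_f1=0.0)
    val_scores = clf.scores(Xva)
    thr, f1 = calibrate_threshold(val_scores, yva)
    clf.threshold = thr
    clf.val_f1 = f1
    clf.loss_trace = trace
    return clf


def predict(clf: TrainedClassifier, windows: Sequence[SampleWindow],
            baseline: BaselineModel | None) -> tuple[np.ndarray, np.ndarray]:
    """Scores and boolean methylation calls (score >= calibrated threshold)."""
    feats, _, _ = feature_tensor(windows, clf.strategy, baseline)
    scores = clf.scores(feats)
    return scores, scores >= clf.threshold
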