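"""Labeled sample windows: a 41-bp sequence centered on a candidate base and
the aligned 21-bp kinetic vectors for the central region.

Only the central 21 bases carry classification signal; the extra 10-bp flanks
exist so the frozen baseline regressor (which itself needs a 21-bp context)
can predict kinetics for every central position.  Index conventions: the
candidate base is seq41[20] and kin21[10]; kin21[i] is aligned with
seq41[i + 10].

Minus-strand sites are represented in the strand's own reading direction:
seq41 is the reverse complement of the genomic window and the kinetic vectors
are taken from the minus-strand track in matching orientation.

Sampling follows the train/test asymmetry of methylation benchmarks built on
native + WGA sample pairs: training negatives are the *same motif's*
instances in WGA (methylation-free) data, so sequence composition cannot
separate the classes; test negatives are random motif-free positions with the
same central base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .simdata import (IUPAC, MethylSite, MethylationTruth, SimulatedKinetics,
                      find_motif_sites, reverse_complement)

logger = logging.getLogger(__name__)

FLANK = 20          # sequence flank: |seq41| = 2*FLANK + 1
KIN_FLANK = 10      # kinetic flank:  |kin21| = 2*KIN_FLANK + 1

__all__ = [
    "SampleWindow", "SamplingPlan", "KineticDataset",
    "extract_window", "build_training_set", "build_test_set",
    "split_sites", "windows_to_table", "windows_from_table",
]


@dataclass
class SampleWindow:
    seq41: str
    kin21_ipd: np.ndarray
    kin21_pw: np.ndarray
    strand: str
    label: str                    # methylated | unmethylated | unknown
    origin: str                   # native | wga | random_negative
    contig: str = "sim_contig"
    pos: int = -1                 # genomic position of the candidate base

    def __post_init__(self) -> None:
        if len(self.seq41) != 2 * FLANK + 1:
            raise ValueError(f"seq41 must have length {2 * FLANK + 1}")
        self.kin21_ipd = np.asarray(self.kin21_ipd, dtype=float)
        self.kin21_pw = np.asarray(self.kin21_pw, dtype=float)
        if len(self.kin21_ipd) != 2 * KIN_FLANK + 1 or len(self.kin21_pw) != 2 * KIN_FLANK + 1:
            raise ValueError(f"kinetic vectors must have length {2 * KIN_FLANK + 1}")

    @property
    def center_base(self) -> str:
        return self.seq41[FLANK]

    def site_key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.strand)


@dataclass
class SamplingPlan:
    """How negatives are drawn.

    train mode pairs native positives with WGA instances of the same motif;
    test mode pairs them with random motif-free loci.  ``exclusion_radius``
    keeps that much sequence around a random negative free of known modified
    bases (default 20 bp: the whole 41-bp context is motif-free).
    """

    mode: str = "train"
    negative_source: str = "wga_same_motif"
    balance: bool = True
    exclusion_radius: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("train", "test"):
            raise ValueError("mode must be 'train' or 'test'")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")
        expected = "wga_same_motif" if self.mode == "train" else "random_non_motif"
        if self.negative_source != expected:
            raise ValueError(
                f"{self.mode} mode requires negative_source={expected!r}")


@dataclass
class KineticDataset:
    """A genome plus its (normalized) kinetics, the unit windows are cut from."""

    genome: dict[str, str]
    kinetics: SimulatedKinetics | pd.DataFrame
    truth: MethylationTruth | None = None
    _arrays: dict = field(default_factory=dict, repr=False)

    def strand_arrays(self, contig: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Genome-length (ipd, pw) arrays with NaN where no record exists."""
        key = (contig, strand)
        if key in self._arrays:
            return self._arrays[key]
        L = len(self.genome[contig])
        if isinstance(self.kinetics, SimulatedKinetics):
            if self.kinetics.contig != contig:
                raise KeyError(contig)
            ipd = self.kinetics.ipd[strand]
            pw = self.kinetics.pw[strand]
        else:
            ipd = np.full(L, np.nan)
            pw = np.full(L, np.nan)
            sel = self.kinetics[(self.kinetics["contig"] == contig)
                                & (self.kinetics["strand"] == strand)]
            ipd[sel["pos0"].to_numpy()] = sel["ipd_mean"].to_numpy()
            pw[sel["pos0"].to_numpy()] = sel["pw_mean"].to_numpy()
        self._arrays[key] = (ipd, pw)
        return ipd, pw


def extract_window(dataset: KineticDataset, site: MethylSite,
                   label: str = "unknown", origin: str = "native") -> SampleWindow | None:
    """Cut the 41-bp sequence and aligned 21-bp kinetics around one site.

    Returns None (and counts in the caller) when the site is within FLANK of a
    contig end or any of the 21 central kinetic values is missing.
    """
    seq = dataset.genome[site.contig]
    p = site.pos
    if p < FLANK or p + FLANK >= len(seq):
        return None
    window = seq[p - FLANK: p + FLANK + 1]
    ipd, pw = dataset.strand_arrays(site.contig, site.strand)
    if site.strand == "+":
        kin_pos = np.arange(p - KIN_FLANK, p + KIN_FLANK + 1)
        seq41 = window
    else:
        # minus strand reads 5'->3' in decreasing genomic coordinate
        kin_pos = np.arange(p + KIN_FLANK, p - KIN_FLANK - 1, -1)
        seq41 = reverse_complement(window)
    ki = ipd[kin_pos]
    kp = pw[kin_pos]
    if np.isnan(ki).any() or np.isnan(kp).any():
        return None
    return SampleWindow(seq41, ki, kp, site.strand, label, origin,
                        contig=site.contig, pos=p)


def _extract_all(dataset: KineticDataset, sites: Sequence[MethylSite],
                 label: str, origin: str) -> list[SampleWindow]:
    out, dropped = [], 0
    for s in sites:
        w = extract_window(dataset, s, label, origin)
        if w is None:
            dropped += 1
        else:
            out.append(w)
    if dropped:
        logger.info("dropped %d/%d %s sites (edge or missing kinetics)",
                    dropped, len(sites), label)
    return out


def build_training_set(native: KineticDataset, wga: KineticDataset,
                       motif: str, mod_offset: int,
                       plan: SamplingPlan,
                       positive_sites: Sequence[MethylSite] | None = None,
                       ) -> list[SampleWindow]:
    """Positives: modified-base sites from the native data; negatives: the same
    motif's instances in the WGA (methylation-free) data."""
    if plan.mode != "train":
        raise ValueError("build_training_set requires a train-mode plan")
    if positive_sites is None:
        if native.truth is None:
            raise ValueError("native dataset has no methylation truth")
        positive_sites = native.truth.sites
    base = motif[mod_offset]
    if base not in "ACGT":
        raise ValueError("modified base of the motif must be a concrete A/C/G/T")
    pos_windows = _extract_all(native, positive_sites, "methylated", "native")
    neg_sites = []
    for contig, seq in wga.genome.items():
        neg_sites.extend(find_motif_sites(seq, motif, mod_offset, contig))
    neg_windows = _extract_all(wga, neg_sites, "unmethylated", "wga")
    if not pos_windows or not neg_windows:
        raise ValueError(
            f"training set degenerate: {len(pos_windows)} positives, "
            f"{len(neg_windows)} negatives")
    if plan.balance:
        rng = np.random.default_rng(plan.seed)
        n = min(len(pos_windows), len(neg_windows))
        pos_windows = [pos_windows[i] for i in sorted(rng.choice(len(pos_windows), n, replace=False))]
        neg_windows = [neg_windows[i] for i in sorted(rng.choice(len(neg_windows), n, replace=False))]
    return pos_windows + neg_windows


def build_test_set(native: KineticDataset, motif: str, mod_offset: int,
                   plan: SamplingPlan,
                   positive_sites: Sequence[MethylSite] | None = None,
                   ) -> list[SampleWindow]:
    """Positives: native modified-base sites; negatives: random loci whose
    surrounding exclusion window holds no known modified base, sharing the
    positives' central base letter so composition cannot separate classes."""
    if plan.mode != "test":
        raise ValueError("build_test_set requires a test-mode plan")
    if positive_sites is None:
        if native.truth is None:
            raise ValueError("native dataset has no methylation truth")
        positive_sites = native.truth.sites
    base = motif[mod_offset]
    pos_windows = _extract_all(native, positive_sites, "methylated", "native")
    if not pos_windows:
        raise ValueError("no positive windows available")
    if native.truth is None:
        raise ValueError("negative exclusion needs the methylation truth")
    rng = np.random.default_rng(plan.seed)
    n_needed = len(pos_windows) if plan.balance else len(pos_windows)
    neg_windows: list[SampleWindow] = []
    truth_pos: dict[str, np.ndarray] = {}
    for contig in native.genome:
        tp = np.array(sorted({s.pos for s in native.truth.sites if s.contig == contig}),
                      dtype=np.int64)
        truth_pos[contig] = tp
    candidates = []
    for contig, seq in native.genome.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        centers = np.nonzero(arr == base.encode())[0]
        centers = centers[(centers >= FLANK) & (centers < len(seq) - FLANK)]
        tp = truth_pos[contig]
        if len(tp):
            # exclude candidates with any modified base within the radius
            left = np.searchsorted(tp, centers - plan.exclusion_radius, side="left")
            right = np.searchsorted(tp, centers + plan.exclusion_radius, side="right")
            centers = centers[left == right]
        for c in centers:
            candidates.append((contig, int(c)))
    if len(candidates) < n_needed:
        raise ValueError(
            f"insufficient eligible negatives: need {n_needed}, have {len(candidates)}")
    order = rng.permutation(len(candidates))
    for idx in order:
        contig, c = candidates[idx]
        # negatives sit on the plus strand so the central base letter is fixed
        site = MethylSite(contig, c, "+", "neg")
        w = extract_window(native, site, "unmethylated", "random_negative")
        if w is not None:
            neg_windows.append(w)
        if len(neg_windows) == n_needed:
            break
    if len(neg_windows) < n_needed:
        raise ValueError(
            f"insufficient eligible negatives after kinetic filtering: "
            f"need {n_needed}, have {len(neg_windows)}")
    return pos_windows + neg_windows


def random_windows(dataset: KineticDataset, n: int, seed: int,
                   label: str = "unmethylated", origin: str = "wga",
                   ) -> list[SampleWindow]:
    """n seeded random windows (any central base, both strands) with complete
    kinetics — the sampling unit for baseline-regressor training on WGA data."""
    rng = np.random.default_rng(seed)
    candidates: list[tuple[str, int, str]] = []
    for contig, seq in dataset.genome.items():
        for strand in "+-":
            for p in range(FLANK, len(seq) - FLANK):
                candidates.append((contig, p, strand))
    if len(candidates) < n:
        raise ValueError(f"genome too small: {len(candidates)} candidate windows < {n}")
    order = rng.permutation(len(candidates))
    out: list[SampleWindow] = []
    for idx in order:
        contig, p, strand = candidates[idx]
        w = extract_window(dataset, MethylSite(contig, p, strand, "none"), label, origin)
        if w is not None:
            out.append(w)
        if len(out) == n:
            break
    if len(out) < n:
        raise ValueError(f"only {len(out)} of {n} requested windows had complete kinetics")
    return out


def split_sites(sites: Sequence[MethylSite], fraction: float, seed: int,
                ) -> tuple[list[MethylSite], list[MethylSite]]:
    """Seeded disjoint split of sites (e.g. train vs test positives)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sites))
    n_first = int(round(fraction * len(sites)))
    first = [sites[i] for i in sorted(order[:n_first])]
    second = [sites[i] for i in sorted(order[n_first:])]
    return first, second


def windows_to_table(windows: Sequence[SampleWindow]) -> pd.DataFrame:
    """Serialize windows to a flat table (TSV-friendly)."""
    cols: dict[str, list] = {"seq41": [w.seq41 for w in windows]}
    for i in range(2 * KIN_FLANK + 1):
        cols[f"ipd_{i}"] = [float(w.kin21_ipd[i]) for w in windows]
    for i in range(2 * KIN_FLANK + 1):
        cols[f"pw_{i}"] = [float(w.kin21_pw[i]) for w in windows]
    cols["strand"] = [w.strand for w in windows]
    cols["label"] = [w.label for w in windows]
    cols["origin"] = [w.origin for w in windows]
    cols["contig"] = [w.contig for w in windows]
    cols["pos"] = [w.pos for w in windows]
    return pd.DataFrame(cols)


def windows_from_table(df: pd.DataFrame) -> list[SampleWindow]:
    k = 2 * KIN_FLANK + 1
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(SampleWindow(
            d["seq41"],
            np.array([d[f"ipd_{i}"] for i in range(k)]),
            np.array([d[f"pw_{i}"] for i in range(k)]),
            d["strand"], d["label"], d["origin"], d["contig"], int(d["pos"]),
        ))
    return out
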