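"""Metrics and statistical comparison machinery.

Threshold-free discrimination is summarized by ROC AUC (equivalently the
Mann-Whitney U statistic scaled by n_pos * n_neg, ties counted one half) and
AUPR (average precision with step interpolation).  Thresholded metrics
(accuracy, precision, recall) come from the 2x2 confusion at the calibrated
decision threshold.

Two paired score vectors on the same samples are compared with DeLong's test
for correlated ROC curves (structural-components formulation with midranks);
groups of per-round AUCs are compared with the Mann-Whitney U test (exact for
small samples).  Repeated evaluation uses seeded re-partitioning of the
training pool into train/validation splits while the test set stays fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport", "BootstrapPlan",
    "roc_auc", "pr_metrics", "evaluate_scores",
    "delong_test", "compare_strategies", "bootstrap_evaluate",
]


@dataclass
class EvalReport:
    auc: float
    acc: float
    precision: float
    recall: float
    aupr: float
    threshold: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("auc", "acc", "precision", "recall", "aupr", "threshold",
                 "n_pos", "n_neg")}


@dataclass
class BootstrapPlan:
    """Repeated seeded train/validation re-partitioning (test set fixed)."""

    n_rounds: int = 10
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")

    def round_seeds(self) -> list[int]:
        rng = np.random.default_rng(self.seed)
        return [int(s) for s in rng.integers(0, 2 ** 31, size=self.n_rounds)]


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals U / (n_pos * n_neg) with ties at 1/2."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_metrics(scores: Sequence[float], labels: Sequence[int], threshold: float,
               ) -> tuple[float, float, float, float]:
    """(acc, precision, recall, aupr) at a decision threshold.

    Precision with zero predicted positives is defined as 0 with a warning;
    AUPR is threshold-free average precision.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("empty input")
    _check_two_classes(labels)
    calls = scores >= threshold
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    acc = (tp + tn) / len(labels)
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    aupr = float(average_precision_score(labels, scores))
    return acc, precision, recall, aupr


def evaluate_scores(scores: Sequence[float], labels: Sequence[int],
                    threshold: float = 0.5) -> EvalReport:
    labels = np.asarray(labels)
    acc, precision, recall, aupr = pr_metrics(scores, labels, threshold)
    return EvalReport(
        auc=roc_auc(scores, labels), acc=acc, precision=precision,
        recall=recall, aupr=aupr, threshold=threshold,
        n_pos=int(np.sum(labels == 1)), n_neg=int(np.sum(labels == 0)))


# --------------------------------------------------------------------------
# DeLong's test for two correlated AUCs


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged) of a 1-D array."""
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray,
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and its structural components V10 (per positive), V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int]) -> tuple[float, float, float, float]:
    """DeLong's two-sided test for paired ROC curves.

    Returns (auc_a, auc_b, z, p).  Zero estimated variance of the AUC
    difference (e.g. identical score vectors) yields p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must have equal length")
    _check_two_classes(labels)
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        logger.info("delong_test: zero variance of AUC difference; p = 1")
        return float(auc_a), float(auc_b), 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(min(p, 1.0))


def delong_variance(scores: Sequence[float], labels: Sequence[int]) -> float:
    """DeLong variance estimate of a single AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    _, v10, v01 = _delong_components(scores, labels)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def compare_strategies(aucs_a: Sequence[float], aucs_b: Sequence[float],
                       ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two groups of per-round AUCs.

    Exact p for small samples (<= 20 total without ties), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    small = (a.size + b.size) <= 20
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if small and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bootstrap_evaluate(
    train_pool: Sequence,
    test_windows: Sequence,
    test_labels: Sequence[int],
    plan: BootstrapPlan,
    train_fn: Callable[[Sequence, Sequence, int], tuple[np.ndarray, float]],
) -> tuple[list[EvalReport], EvalReport]:
    """Repeated train/validation re-partitioning with a fixed test set.

    ``train_fn(train_split, val_split, seed)`` must return
    ``(test_scores, threshold)`` for the fixed test set.  Failed rounds are
    logged and skipped; returns (per-round reports, arithmetic-mean report).
    """
    test_labels = np.asarray(test_labels)
    reports: list[EvalReport] = []
    for rnd, seed in enumerate(plan.round_seeds()):
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(train_pool))
        n_train = int(round(plan.train_fraction * len(train_pool)))
        tr = [train_pool[i] for i in order[:n_train]]
        va = [train_pool[i] for i in order[n_train:]]
        try:
            scores, threshold = train_fn(tr, va, seed)
            reports.append(evaluate_scores(scores, test_labels, threshold))
        except Exception:
            logger.exception("bootstrap round %d failed; continuing", rnd)
    if not reports:
        raise RuntimeError("all bootstrap rounds failed")
    mean = EvalReport(
        auc=float(np.mean([r.auc for r in reports])),
        acc=float(np.mean([r.acc for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        aupr=float(np.mean([r.aupr for r in reports])),
        threshold=float(np.mean([r.threshold for r in reports])),
        n_pos=reports[0].n_pos, n_neg=reports[0].n_neg)
    return reports, mean
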