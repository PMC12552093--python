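"""Reproducible simulation studies bundled with the package.

These functions define the package's standard synthetic benchmarks — the
conditions under which the two-stage framework is exercised end to end:

* ``train_shared_baseline`` — one polymerase chemistry, one WGA genome, one
  baseline regressor trained at the recovery-study scale (20k train / 5k
  held-out windows, subread noise sigma 0.2, 7-mer ground-truth contexts).
  The same frozen regressor serves every downstream study, as a single
  WGA-trained model serves all native datasets of one chemistry.
* ``weak_signal_round`` — the 5mC-like regime: a dense CpG-style motif with
  partial methylation and a weak multiplicative kinetic shift; strategies 6
  (difference + ratio + sequence) and 7 (raw + sequence, the no-baseline
  ablation) are trained and scored on a fresh native genome per round.
* ``strong_signal_round`` — the 6mA-like regime: GATC with full methylation
  and a strong shift, where both strategies are expected to approach perfect
  discrimination.
* ``delong_null_calibration`` — type-I error of DeLong's test under a
  simulated null.
* ``attribution_locality`` — integrated-gradients mass inside vs outside the
  generative model's true context window.

Every function is deterministic given its seed; sub-seeds are drawn from a
``numpy`` SeedSequence so studies are independent but reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simdata import (SimConfig, GroundTruthKinetics, simulate_dataset,
                      WEAK_5MC_PRESET, STRONG_6MA_PRESET)
from .kinetics_io import NormalizationSpec, normalize_table
from . import windows as win
from .baseline_regressor import (BaselineModel, RegressorConfig,
                                 integrated_gradients, regression_training_data,
                                 train_regressor)
from .classifier import ClassifierConfig, train_classifier, predict
from .evaluation import delong_test, roc_auc

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# Study scales.  Chosen once as the package's standard benchmark sizes: large
# enough for the classifier regimes to be stable across seeds, small enough
# to run on a laptop CPU.
WGA_GENOME_LENGTH = 150_000
REGRESSOR_TRAIN_N = 20_000
REGRESSOR_TEST_N = 5_000
WEAK_GENOME_LENGTH = 60_000
STRONG_GENOME_LENGTH = 250_000
TEST_POSITIVE_CAP = 600
CONTEXT_K = 7
NOISE_SIGMA = 0.2

_NORM = NormalizationSpec()


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


@dataclass
class SharedBaseline:
    """The frozen regressor plus everything needed to reuse or audit it."""

    model: BaselineModel
    wga_dataset: win.KineticDataset
    chemistry_seed: int
    test_seqs: list[str]
    r_ipd: float
    r_pw: float
    r2_ipd: float
    r2_pw: float
    final_mse: float
    n_train: int
    n_test: int


def _pearson_r2(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    r = float(np.corrcoef(pred, truth)[0, 1])
    ss_res = float(np.sum((truth - pred) ** 2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    return r, 1.0 - ss_res / ss_tot


def train_shared_baseline(seed: int, epochs: int = 50, gru_hidden: int = 64,
                          ) -> SharedBaseline:
    """WGA simulation + baseline-regressor training at the recovery scale.

    Held-out quality is measured against the *noiseless* ground-truth
    kinetics of the test windows' contexts, on the normalized scale (the
    normalization constant is a single track-wide factor, so Pearson r is
    unaffected; R^2 is computed after rescaling truth by the same factor).
    """
    s_chem, s_genome, s_windows, s_train = _subseeds(seed, 4)
    wga_cfg = SimConfig(genome_length=WGA_GENOME_LENGTH, motif="CG", mod_offset=0,
                        methyl_fraction=0.0, context_k=CONTEXT_K,
                        subread_noise_sigma=NOISE_SIGMA,
                        seed=s_genome, chemistry_seed=s_chem)
    seq, _, kin = simulate_dataset(wga_cfg)
    table_raw = kin.to_table()
    dataset = win.KineticDataset({wga_cfg.contig: seq},
                                 normalize_table(table_raw, _NORM), None)
    all_windows = win.random_windows(dataset, REGRESSOR_TRAIN_N + REGRESSOR_TEST_N,
                                     seed=s_windows)
    train_w = all_windows[:REGRESSOR_TRAIN_N]
    test_w = all_windows[REGRESSOR_TRAIN_N:]
    seqs, targets = regression_training_data(train_w)
    model = train_regressor(seqs, targets, RegressorConfig(
        epochs=epochs, gru_hidden=gru_hidden, seed=s_train))

    gt = GroundTruthKinetics(CONTEXT_K, s_chem)
    test_seqs, _ = regression_training_data(test_w)
    pred = model.predict(test_seqs)
    flank = CONTEXT_K // 2
    mid = len(test_seqs[0]) // 2
    codes = np.array([[_BASE_INDEX[b] for b in s[mid - flank: mid + flank + 1]]
                      for s in test_seqs])
    nl_ipd, nl_pw = gt.values_for_codes(codes)
    # put noiseless truth on the same normalized scale as the training targets
    scale_i = table_raw["ipd_mean"].mean()
    scale_p = table_raw["pw_mean"].mean()
    # subread noise is lognormal, so the observed track mean carries the
    # exp(sigma^2/2) factor relative to the noiseless values
    noise_factor = np.exp(NOISE_SIGMA ** 2 / 2.0)
    nl_ipd_n = nl_ipd * noise_factor / scale_i
    nl_pw_n = nl_pw * noise_factor / scale_p
    r_i, r2_i = _pearson_r2(pred[:, 0], nl_ipd_n)
    r_p, r2_p = _pearson_r2(pred[:, 1], nl_pw_n)
    return SharedBaseline(
        model=model, wga_dataset=dataset, chemistry_seed=s_chem,
        test_seqs=test_seqs, r_ipd=r_i, r_pw=r_p, r2_ipd=r2_i, r2_pw=r2_p,
        final_mse=model.loss_trace[-1], n_train=len(train_w), n_test=len(test_w))


def _classification_round(shared: SharedBaseline, native_cfg: SimConfig,
                          seed: int, strategies: tuple[int, ...] = (6, 7),
                          classifier_epochs: int = 25,
                          ) -> dict:
    """One train/test round of the methylation classifier per strategy.

    Positives come from the native simulation's truth, training negatives
    from the shared WGA data's instances of the same motif, test negatives
    from random motif-free loci; the test set is class-balanced.
    """
    s_split, s_plan_tr, s_plan_te, s_part, s_clf = _subseeds(seed, 5)
    seq, truth, kin = simulate_dataset(native_cfg)
    native = win.KineticDataset({native_cfg.contig: seq},
                                normalize_table(kin.to_table(), _NORM), truth)
    tr_pos, te_pos = win.split_sites(truth.sites, 0.6, s_split)
    train_set = win.build_training_set(
        native, shared.wga_dataset, native_cfg.motif, native_cfg.mod_offset,
        win.SamplingPlan(seed=s_plan_tr), positive_sites=tr_pos)
    test_set = win.build_test_set(
        native, native_cfg.motif, native_cfg.mod_offset,
        win.SamplingPlan(mode="test", negative_source="random_non_motif",
                         seed=s_plan_te),
        positive_sites=te_pos[:TEST_POSITIVE_CAP])
    labels = np.array([1 if w.label == "methylated" else 0 for w in test_set])
    rng = np.random.default_rng(s_part)
    order = rng.permutation(len(train_set))
    n_tr = int(round(0.8 * len(train_set)))
    tr = [train_set[i] for i in order[:n_tr]]
    va = [train_set[i] for i in order[n_tr:]]
    out: dict = {"n_train": len(train_set), "n_test": len(test_set),
                 "labels": labels, "scores": {}, "auc": {}}
    for sid in strategies:
        baseline = shared.model if sid != 7 else None
        clf = train_classifier(tr, va, sid, baseline, ClassifierConfig(
            epochs=classifier_epochs, gru_hidden=32, seed=s_clf))
        scores, _ = predict(clf, test_set, baseline)
        out["scores"][sid] = scores
        out["auc"][sid] = roc_auc(scores, labels)
    return out


def weak_signal_round(shared: SharedBaseline, seed: int,
                      strategies: tuple[int, ...] = (6, 7)) -> dict:
    """5mC-like regime: dense CpG motif, 35% methylated, weak kinetic shift."""
    s_sim, s_round = _subseeds(seed, 2)
    cfg = SimConfig(genome_length=WEAK_GENOME_LENGTH, motif="CG", mod_offset=0,
                    methyl_fraction=0.35, context_k=CONTEXT_K,
                    subread_noise_sigma=NOISE_SIGMA, seed=s_sim,
                    chemistry_seed=shared.chemistry_seed,
                    ipd_shift=WEAK_5MC_PRESET["ipd"],
                    pw_shift=WEAK_5MC_PRESET["pw"])
    return _classification_round(shared, cfg, s_round, strategies)


def strong_signal_round(shared: SharedBaseline, seed: int,
                        strategies: tuple[int, ...] = (6, 7)) -> dict:
    """6mA-like regime: GATC fully methylated with a strong kinetic shift."""
    s_sim, s_round = _subseeds(seed, 2)
    cfg = SimConfig(genome_length=STRONG_GENOME_LENGTH, motif="GATC", mod_offset=1,
                    methyl_fraction=1.0, context_k=CONTEXT_K,
                    subread_noise_sigma=NOISE_SIGMA, seed=s_sim,
                    chemistry_seed=shared.chemistry_seed,
                    ipd_shift=STRONG_6MA_PRESET["ipd"],
                    pw_shift=STRONG_6MA_PRESET["pw"])
    return _classification_round(shared, cfg, s_round, strategies)


def delong_null_calibration(seed: int, n_datasets: int = 1000,
                            n_per_class: int = 100, alpha: float = 0.05) -> float:
    """Empirical type-I error of DeLong's test under independent random scores."""
    rng = np.random.default_rng(seed)
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    rejections = 0
    for _ in range(n_datasets):
        a = rng.normal(size=2 * n_per_class)
        b = rng.normal(size=2 * n_per_class)
        _, _, _, p = delong_test(a, b, labels)
        if p < alpha:
            rejections += 1
    return rejections / n_datasets


def attribution_locality(shared: SharedBaseline, n_sequences: int = 50,
                         n_steps: int = 64, seed: int = 0) -> dict:
    """Integrated-gradients locality on the known generative model.

    Only the central ``CONTEXT_K``-mer determines the ground-truth kinetics,
    so attribution mass (mean per-position |score|, averaged over sequences)
    outside that window should be small relative to inside.  Also returns the
    worst completeness gap (relative to the prediction displacement)
    observed across all profiles.
    """
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(shared.test_seqs), size=n_sequences, replace=False)
    window = len(shared.test_seqs[0])
    mid = window // 2
    flank = CONTEXT_K // 2
    inside = np.zeros(window, dtype=bool)
    inside[mid - flank: mid + flank + 1] = True
    worst_gap = 0.0
    ratios = {}
    for target in ("ipd", "pw"):
        profiles = []
        for idx in pick:
            prof = integrated_gradients(shared.model, shared.test_seqs[idx],
                                        target=target, n_steps=n_steps)
            profiles.append(prof.scores)
            denom = max(abs(prof.prediction - prof.baseline_prediction), 1e-9)
            worst_gap = max(worst_gap, prof.completeness_gap / denom)
        mag = np.abs(np.stack(profiles)).mean(axis=0)
        ratios[target] = float(mag[~inside].mean() / mag[inside].mean())
    return {"outside_over_inside_ipd": ratios["ipd"],
            "outside_over_inside_pw": ratios["pw"],
            "outside_over_inside": max(ratios.values()),
            "worst_relative_completeness_gap": worst_gap}
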