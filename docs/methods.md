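# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `smrtkin`. It describes what the code
computes; every number quoted as an expectation is recomputed by the test
suite or by `scripts/acceptance.py`, never hard-coded.

## The two-stage model

**Problem.** Given a genomic window centered on a candidate base, with
per-site polymerase kinetics (inter-pulse duration IPD and pulse width PW)
averaged over subreads, decide whether the center base is methylated. The
difficulty is that kinetics depend far more on local sequence context than on
methylation — for 5mC the methylation effect is a small perturbation on a
large context-dependent baseline.

**Stage 1 — unmethylated-signal regression.** A BiGRU encoder reads the
one-hot 21-bp window (channels ordered A, C, G, T; N encodes as all-zeros);
the two directions' final hidden states are concatenated and passed to two
independent linear heads predicting the center base's normalized IPD and PW.
Training is MSE on WGA (whole-genome amplified, methylation-free) samples:
50 epochs, Adam, learning rate 10⁻³, batch 64. After training the model is
frozen — its predictions define the unmethylated baseline and must not drift
during classifier training (the test suite asserts bit-identical predictions
before and after).

**Stage 2 — classification.** For a candidate site, the 41-bp sequence
window provides enough flanking context that the frozen regressor can predict
baselines for each of the central 21 positions (41 = 21 + 2×10). Per-position
channels are assembled by one of nine integration strategies:

| ID | channels | count |
|----|----------|-------|
| 1 | difference (raw − predicted), IPD + PW | 2 |
| 2 | ratio (raw / predicted) | 2 |
| 3 | difference + ratio | 4 |
| 4 | difference + sequence | 6 |
| 5 | ratio + sequence | 6 |
| 6 | difference + ratio + sequence | 8 |
| 7 | raw + sequence (no baseline — the ablation) | 6 |
| 8 | raw + predicted, concatenated directly | 4 |
| 9 | raw + predicted + sequence | 8 |

The classifier is a BiGRU over the 21×C block with a 2-logit softmax head.
Two architectures share the training recipe: *early concatenation* (one
encoder over all channels) and *late fusion* (one BiGRU branch per modality
group — raw, baseline-referenced, sequence — with final states concatenated
before the head). Late fusion is intended for settings where the predicted
baseline is noisy, so a degraded modality cannot corrupt the others'
representations. Channels are assigned to branches by their modality tag in
the feature layout; strategy 6 under late fusion therefore has a
baseline-referenced branch (difference + ratio) and a sequence branch, while
strategy 9 has raw, predicted and sequence branches.

**Loss.** Focal loss `FL(p_t) = −(1−p_t)^γ log(p_t)` with focusing parameter
γ = 2, composed with label smoothing (factor 0.1) as the target-weighted sum
over the two classes: `L = −Σ_c t_c (1−p_c)^γ log p_c`, with `t =
(0.05, 0.95)` for a methylated label. With hard targets and γ = 0 this is
ordinary cross-entropy (asserted in tests). Probabilities are clamped at
10⁻⁷ before the log. Optimization is Adam at 10⁻³ with step decay ×0.5 every
10 epochs (`lr(e) = lr₀·0.5^⌊e/10⌋`, epoch 0-based).

**Threshold calibration.** Instead of a fixed 0.5 cutoff, the decision
threshold maximizes F1 on a validation split; candidates are midpoints of
consecutive sorted unique scores plus the {0, 1} boundaries, ties resolving
to the lowest threshold; all-equal scores fall back to 0.5 with a warning.

## Sampling rules

Positive samples are windows centered on truth-methylated bases. Negatives
differ between training and testing, which is the property that makes the
ablation (strategy 7) meaningful:

* **Training** negatives are the *same motif's* instances in WGA data. Both
  classes then share sequence composition, so the classifier cannot learn a
  motif detector; it must use the kinetics.
* **Testing** negatives are random loci whose surrounding 20-bp radius
  contains no known modified base, constrained to carry the same central base
  letter as the motif's modified base, sampled seeded and class-balanced.

Windows within 20 bp of a contig end, or missing any of the 21 central
kinetic records, are dropped (counted in logs). Minus-strand windows are
represented in the strand's own 5'→3' direction: the sequence is
reverse-complemented and the kinetic vectors are read from the minus-strand
track in matching orientation. Train/test positive sites are made disjoint by
a seeded split before sampling.

## Normalization

Raw kinetic signals are brought onto a common scale before modeling. The
default is mean scaling — dividing by the group mean — because it keeps
values positive, which the ratio feature requires; z-scoring is available as
an option. On per-site tables the grouping is the whole track (per contig);
when subread-level groups are available, per-read scoping applies. Subread
measurements of one site are combined by the arithmetic mean; sites below a
configurable coverage floor (default 3) are flagged.

## The synthetic-data generator

`simdata` emulates the structure of SMRT kinetic data without claiming real
polymerase chemistry:

* **Ground-truth kinetic function.** The noiseless (IPD, PW) of a base is a
  log-linear function of its k-mer context (default k = 7): per-position base
  effects + adjacent-dinucleotide interaction effects + a small per-k-mer
  residual, drawn once from a seeded normal on the log scale with total
  log-sd ≈ 0.35 (median 1.0). The compositional form gives the regression
  stage learnable but non-trivial structure — position and pair effects are
  recoverable from data, the residual is an explicit noise floor. The
  function is controlled by a dedicated `chemistry_seed`: native and WGA
  datasets of one experiment must share it (amplification removes
  methylation, not the polymerase), while genome and noise seeds vary freely.
* **Methylation effects** are multiplicative at configured offsets from the
  modified base, applied on the modified strand only (prokaryotic methylation
  is often strand-asymmetric). Two presets bracket the regimes: *weak*
  (5mC-like; IPD ×1.15 at offset 0, ×1.07 at +1, PW ×1.08) and *strong*
  (6mA/4mC-like; IPD ×2.5 / ×1.5, PW ×1.4). These are stand-ins chosen to
  reproduce weak/strong signal regimes qualitatively, not estimates of real
  effect sizes.
* **Observation model.** Subread value = noiseless × exp(ε), ε ~ N(0, σ)
  (default σ = 0.2); subread count per site ~ 1 + Poisson(mean − 1) (default
  mean 10); the emitted per-site value is the subread mean. σ = 0 with
  coverage 1 reproduces the noiseless values exactly (tested).

What the simulator does **not** model: sequencing errors, alignment
artifacts, coverage biases along the genome, platform-specific kinetic
distributions, partial methylation within one molecule. Passing tests
therefore demonstrate that the architecture and pipeline recover the intended
signal structure under controlled conditions, not that the tool reaches any
particular accuracy on real PacBio data.

## Bundled simulation studies (`experiments`)

The studies fix the package's standard benchmark sizes (chosen once as a
compromise between stability across seeds and laptop-CPU runtime; the
acceptance script prints every number it computes):

* **Recovery study.** One 150-kb WGA genome; 20,000 training and 5,000
  held-out windows; the regressor's predictions are compared with the
  *noiseless* ground truth of the held-out contexts (Pearson r and R², after
  placing the truth on the normalized scale — mean scaling is one constant
  per track, and the lognormal noise contributes a known exp(σ²/2) factor to
  that constant). Expected behavior: r well above 0.85 for both channels.
* **Weak (5mC-like) regime.** A dense CpG-style motif (`CG`, 35% of sites
  methylated) on a fresh 60-kb native genome per round, weak preset, shared
  chemistry and regressor; strategies 6 and 7 are trained per round
  (classifier: hidden 32, 25 epochs) and scored on a balanced test set
  (≤600 positives). The dense, diverse contexts are exactly what defeats the
  raw+sequence ablation: raw kinetics spread over the full context
  variability while the baseline-referenced features isolate the small
  shift. Expected behavior over five paired rounds: strategy 6 wins every
  pair; strategy 7 stays near chance.
* **Strong (6mA-like) regime.** `GATC` fully methylated on a 250-kb genome,
  strong preset: both strategies are expected to exceed AUC 0.95 — with
  signals this large the baseline reference adds little, matching the
  intended "strong signal" behavior.
* **DeLong calibration.** 1,000 null datasets (two independent random score
  vectors, 100 samples per class): the empirical rejection rate at α = 0.05
  should sit in [0.03, 0.07].
* **Attribution locality.** Integrated gradients (midpoint Riemann sum over
  a straight path from the baseline input; default 64 steps, 128 in the
  diagnostics) must satisfy completeness — attributions summing to
  f(x) − f(baseline) within 1% — and concentrate on the true 7-mer context
  window, since nothing outside that window influences the generative model:
  mean |attribution| per position outside the window below 10% of inside.
  The choice of baseline input matters here. The default is the
  maximum-entropy composition (0.25 per channel), which stays near the data
  manifold; the all-zeros (all-N) baseline is also available, but an all-N
  input lies far outside anything the model saw, so the path assigns every
  position a content-independent share of the constant displacement
  f(x) − f(0) — empirically ~0.2–0.4 outside/inside even for an essentially
  exact model, versus ~0.03 from the uniform baseline at identical
  completeness. That leakage is a property of the estimator's path, not of
  the model (a flank-occlusion probe on the same models shows ≤10%
  functional sensitivity).

## Numerical and design choices

* **Neural-network core.** The BiGRU, dense layers, Adam and both losses are
  a compact vectorized numpy implementation with hand-derived backward passes
  (gate order r, z, n; the candidate's recurrent term carries its own bias,
  applied before the reset gate). All gradients are verified against central
  finite differences in the test suite. When numba is importable the
  recurrence runs through compiled kernels that are exact (to machine
  precision) matches of the numpy path.
* **Hidden sizes.** Regressor: hidden 64, dropout 0.2 (inverted, on the
  encoder output, training only). Classifier: hidden 32 in the studies.
  Small windows need modest capacity; larger models overfit the small sample
  sets long before they help.
* **Convergence vs. dataset size.** With step-decayed Adam, what matters is
  optimization *steps*, not epochs; on small sample sets the bundled studies
  and tests raise epochs (and stretch the decay interval) to keep the step
  count in the low thousands. The defaults (50 regressor epochs, batch 64)
  are tuned to the study scales above.
* **Ratio guard.** `raw / max(predicted, 10⁻³)`: under mean scaling the
  predicted baseline hovers near 1, so the clamp only guards pathology.
* **Coordinates** are 0-based, half-open everywhere; truth BED intervals have
  width 1. Strands are `+`/`-`; one record per (contig, position, strand).
* **AUPR** is average precision (step interpolation), matching the standard
  implementation; ROC AUC equals the Mann-Whitney U statistic scaled by
  n₊·n₋ with ties counted ½ (asserted against an O(n²) pair-count oracle).
* **DeLong's test** uses the structural-components formulation with midranks
  (O(n log n)); zero estimated variance of the AUC difference (identical
  score vectors) returns p = 1 with a log note. Checked against a stratified
  bootstrap and for type-I calibration.
* **"Bootstrap" evaluation** means repeated seeded re-partitioning of the
  training pool into train/validation splits with a fixed test set (80/20 by
  default), and arithmetic means over rounds.
* **Mann-Whitney strategy comparison** uses the exact distribution for ≤20
  total tie-free observations, otherwise the tie-corrected normal
  approximation.
* **Degenerate inputs**: single-class training or validation sets, empty
  groups, all-equal calibration scores, non-finite losses and malformed
  kinetics rows all raise (or warn) explicitly rather than propagating.

## Limitations

* Real bax.h5/BAM kinetic extraction is out of scope; the package ingests a
  tabular kinetics endpoint (TSV) that stands in for the output of such
  extraction pipelines.
* The supplementary-level normalization recipe of production pipelines is not
  reproduced; mean scaling per track is this package's documented default.
* Simulator presets are qualitative regimes, not chemistry estimates; real
  5mC offsets differ by motif and polymerase.
* Class-balanced test sets overstate precision relative to genome-wide
  deployment, where unmethylated sites dominate; calibrate thresholds
  accordingly before genome-wide calling.
* Training runs on CPU only; the studies' model sizes are chosen for that.
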