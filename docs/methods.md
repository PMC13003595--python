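# Methods

This note records the model, the synthetic-data generator, the
numerical choices, and the places where the design was genuinely open
and a decision had to be made. It states no empirical result the test
suite or `scripts/acceptance.py` does not itself compute.

## The network

HIBPN is a modular MLP over three feature blocks:

| block | features | encoder |
|---|---|---|
| human-environment | gender, age, basic-needs total, estimated catch %, trait-group indicators, condition indicator (reverse chain only) | two layers: upscale (default width 32), then downscale (8), ReLU |
| narcissism | NPI-16 total, HSNS total | one upscaling layer (8), ReLU |
| hostile interpretation | hostile total, non-hostile total | one layer (4), ReLU; forward chain only |

The fused vector `A_hen = A_he ⊕ A_n` feeds the reverse head (hidden
width 16, ReLU; a linear regression output and a sigmoid
classification output on the high/low hostile bin). The further fusion
`A_all = A_hen ⊕ A_h,mid` feeds the forward head (hidden width 16).
Both the forward head's hidden layer and its output are sigmoid; all
other hidden layers are ReLU. Upscale/downscale width inequalities
(`he_up > he_in > ... `, `narc_up > narc_in`) are enforced at
construction.

Open points resolved as design choices:

* **Layer widths** are not dictated by the design; the defaults above
  suit cohorts of a few hundred and are all configurable
  (`HibpnDims`).
* **The hostile-interpretation intermediate feature** `A_h,mid` has no
  prescribed construction; a one-layer ReLU encoder of the
  standardized (hostile, non-hostile) pair is the minimal faithful
  reading.
* **Reverse-chain duality.** The reverse chain's defining output is
  continuous and unbounded, yet it is evaluated with classification
  metrics. The implementation keeps both: the regression head exactly
  as defined (trained with an auxiliary MSE term, weight 0.5, on
  z-scored hostile totals) and a sigmoid head on the high/low bin used
  for ACC/F1/AUC. Classification mode is the default in experiments.
* **Anti-leakage.** The condition indicator is excluded from forward
  inputs and included in reverse inputs; a test verifies that
  permuting condition labels changes no forward prediction.
* **Standardization.** Continuous inputs are z-scored with
  training-set statistics; categorical inputs are 0/1 indicators.

## Training

Full-batch gradient descent, fixed learning rate 0.3, 500 epochs,
binary cross-entropy; chains are trained independently with no weight
sharing. With ~26 training records (10% of 258) stochastic
mini-batching adds nothing, and full-batch descent makes the
loss-monotonicity property testable (it is, at small learning rates).
Initialization is He-normal for ReLU layers, Glorot-normal for
sigmoid/linear layers, zero biases, all from a seeded generator; every
stage of the pipeline is a deterministic function of its seed.

The 1:9 ratio is read as train:test = 10%:90% — the protocol
deliberately stresses generalization. `split_1_9` uses
largest-remainder stratified allocation on the target label so both
classes appear in a 26-record training set.

Class imbalance is handled in reporting (F1, AUC) rather than by
reweighting.

## The synthetic cohort generator

The generator emulates the between-subjects Cyberball design:

* **Trait groups.** NPI-16 and HSNS totals are drawn from truncated
  normals (NPI ~ N(8, 3) on [0, 16]; HSNS ~ N(30, 6) on [10, 50]) and
  the top-27% / top-27% / middle-46% assignment is *actually run* on
  them, so group labels and scores are consistent by construction.
  Group sizes are round(0.27 n) each; overlap between the two top sets
  goes to the scale with the higher percentile rank (HSNS wins ties),
  with refill so counts stay exact.
* **Cyberball.** Exclusion: exactly 2 catches, placed uniformly among
  the first 15 of 30 passes (the avatars keep the ball to themselves
  in the second half) — a 6.67% catch rate by design. Acceptance: each
  pass reaches the participant independently with probability 1/3.
* **Interpretation scores.** Hostile and non-hostile totals come from
  normals with the published per-cell means/SDs (e.g. dominant ×
  exclusion: hostile 45.65 ± 4.06), truncated to the instrument range
  [12, 60] (12 ambiguous sentences × ratings 1–5) and rounded to
  integers to match summed-Likert semantics. Truncation bias is
  negligible at these parameters (< 0.05 points in every cell).
* **Covariates.** Basic-needs totals are N(75, 10) minus a 10-point
  drop under exclusion (the design treats totals below 60 as marking
  high threat, so a shift of this size is meaningful yet leaves most
  records above the debrief threshold); the subjective catch estimate
  is the true game rate plus N(0, 10) percentage points, clamped to
  [0, 100]; gender is 2:1 male (the intervention experiment's reported
  composition) and age uniform on 19–22. All configurable.
* **Conditions.** 50:50 by default within each trait group. The
  original cell sizes are unreported, so the ratio is exposed rather
  than guessed; `condition_ratio_by_group` additionally allows
  trait-correlated exposure (an observational regime used by the
  ablation-ordering tests to concentrate signal in the narcissism
  features).
* **Intervention cohort.** 18 + 18 participants, all drawn from the
  upper HSNS range, randomised to arms; the affirmation arm's hostile
  cell mean is reduced by the configured effect (default 5 scale
  points, roughly one within-cell SD — a moderate, recoverable shift)
  before sampling.

What the generator does **not** emulate: item-level response patterns
(totals are drawn directly), reliability structure of the instruments,
any real dependence between narcissism scores and condition (absent by
randomisation in the default design), and the original study's
feature–label joint distribution. Consequently the tests show that the
pipeline recovers *planted* structure — cell means, signal directions,
effect monotonicity — not that the published absolute performance
numbers re-emerge; on synthetic cohorts the classical baselines can be
fully competitive with the network.

## Evaluation and analyses

* Metrics delegate to scikit-learn behind the `hibpn.evaluation`
  surface; tests pin them to independent oracles (exhaustive
  concordant-pair counting for AUC, enumerated 2×2 confusion matrices
  for ACC/F1). AUC credits ties one half, making the trapezoidal and
  pair-count definitions identical. F1 is defined as 0, with a
  warning, when no true or predicted positives exist.
* `relative_gap` exposes both denominator conventions found in
  published drop percentages: the reference value (usual) and the
  degraded value itself (used by some accuracy-drop figures). The
  inconsistency is documented, not resolved; the ablation gap table
  reports both.
* **Ablation** removes whole dimension groups (narcissism / hostile
  interpretation) and *retrains* on the identical split — module
  removal, not weight zeroing.
* **Grouped importance** fits a 500-tree random forest surrogate on
  exactly the features the chain sees and sums per-feature importances
  by dimension group. The social-exclusion group comprises basic
  needs and estimated catch (plus the condition indicator in the
  reverse chain); gender and age form a separate demographics group
  that participates in the surrogate fit but is excluded from the
  three-way normalisation to 100%, keeping the report comparable to
  the three-dimension layout. In the reverse chain the
  hostile-interpretation group is empty by design (it is the target)
  and is reported as 0 with a warning.
* **Intervention contrast.** An arm's positive response rate is the
  fraction of its participants the trained forward chain classifies
  as socially accepted (P(exclusion) < 0.5); the contrast is reported
  in percentage points. At the study's 18-per-arm size a single
  participant moves a rate by 5.6 points, so recovery properties
  (positive sign, monotonicity in the planted effect over
  {0, 2.5, 5, 10} points) are tested at 1,000 per arm over 20 seeds.

## Numerical choices and degenerate inputs

* Seeds: every stochastic component takes an explicit seed;
  per-participant game seeds derive from the cohort generator's
  stream. Saved models round-trip bit-exactly through `.npz`.
* QDA with a class covariance that scikit-learn rejects as
  rank-deficient (fewer class samples than features — routine under
  the 1:9 split) falls back to a ridge-regularized quadratic
  discriminant (diagonal loading 1e-6 × mean variance), with a
  warning.
* Degenerate sampling cells (SD 0) return the rounded mean; hostile
  bins use the single cut ≤35 / ≥36 over the full instrument range
  [12, 60], since the published bin edges describe observed data, not
  the instrument.
* Zero-epoch training returns the initialization unchanged; NaN loss
  aborts with a diagnostic naming the epoch.
* Problem sizes in the test suite: cell-mean recovery at n = 10,000
  (3 standard errors plus 0.05 rounding slack); planted-signal
  recovery at n = 2,000 over 20 seeds; null calibration over 5 seeds;
  intervention monotonicity at 1,000 per arm — sizes at which the
  checked effects are well inside sampling noise for a desk-scale run.

## Known limitations

* The reverse chain's regression and classification heads share a
  hidden layer; with very small training sets the auxiliary MSE term
  can dominate early epochs.
* The generator draws totals, not items, so internal-consistency
  phenomena (e.g. reverse-keyed item artefacts) cannot be studied.
* Published absolute performance tables are not reproducible from
  synthetic cohorts and are deliberately not targets; only their
  internal arithmetic (relative gaps, margins, arm-rate differences)
  is reproduced exactly.
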