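# Methods

## Problem setting

`dualscreen` targets a screening task from community primary care: flag
elderly clients at high risk of cognitive impairment — the MMSE-defined
positive class, score < 24 out of 30 — from routinely collected health
records, *without* administering the cognitive questionnaire itself. The
records have two structurally different halves:

* **client profile** (n_p columns): demographics, bio-measurements and
  medical history. Mostly complete, continuous, and expressed in raw
  heterogeneous units (mmHg, °C, beats/min, unit-free ratios).
* **health assessment** (n_q columns): items from pain, mobility,
  depression, nutrition, constipation, daily-living, oral-hygiene, vision
  and activity questionnaires. Largely yes/no or small ordinal scores, and
  heavily incomplete because clients skip appointments or decline
  questions.

Three statistical problems follow, and the package addresses each:
missing data (imputation), group heterogeneity (the dual architecture),
and class imbalance (cost-sensitive learning).

## Imputation

A feature is *complete* if observed for every record, *incomplete*
otherwise. Two fill strategies are provided.

**Mean imputation** replaces each missing cell with the observed mean of
its column.

**KNN imputation** anchors record similarity on the complete features
only: the distance matrix `D` (Euclidean by default; city-block and cosine
are accepted) is computed over complete columns, so missingness never
contaminates the metric. A missing cell (i, b) is filled with a weighted
average of feature b over the k records nearest to i *among those that
observe b*. Design choices the algorithm statement leaves open, fixed
here:

* weights `w_j = 1/(D_ij + 1e-8)`, normalized over the contributing
  neighbors — monotone in similarity, and the epsilon keeps exact
  duplicates (D = 0) finite;
* eligibility is skip-and-extend: the k nearest *observers* of the
  feature, not the k nearest records overall, so k contributors exist
  whenever the column has k observers; with fewer observers all of them
  are used;
* equidistant neighbors are ranked by row index (determinism);
* a column with zero observed values is an error for both methods — there
  is no value to generalize from.

Default `k = 5`. Imputation is applied to the full table before
cross-validation splitting, reproducing the evaluated pipeline's stage
order (fill first, then learn). A leak-free mode (off by default) is
available behind a flag: each training fold is imputed on its own records
only, and the held-out fold is filled *against* the training records —
reference column means, or reference-only neighbor pools
(`impute_against`).

## The dual network

Each feature group gets its own two-hidden-layer ReLU branch:

    h_p = ReLU(ReLU(p W_p1 + b_p1) W_p2 + b_p2)    (n_p -> d1 -> d2)
    h_q = ReLU(ReLU(q W_q1 + b_q1) W_q2 + b_q2)    (n_q -> d1 -> d2)

The concatenation h = [h_p, h_q] (width 2·d2) feeds a sigmoid head
`ŷ = σ(h W_y + b_y)`, the predicted high-risk probability. Variants may
insert one or two extra fully connected ReLU layers between h and the
head; their width defaults to 2·d2 since nothing pins it down.

Training minimizes the mean cross-entropy

    L = mean_i −[ w_i · y_i · log ŷ_i + (1 − y_i) · log(1 − ŷ_i) ]

with `w_i = m^n / m^d` (normal-to-high-risk count ratio in the *training*
samples) for positive cases under cost-sensitive learning, and `w_i = 1`
otherwise. At the emulated class counts (1872 vs 427) the ratio is 4.4.
Probabilities are clamped to `[1e-7, 1 − 1e-7]` inside the loss.

Optimization is mini-batch SGD with momentum 0.9. Defaults: `d1 = 128`,
`d2 = 32`, learning rate 0.01, 200 epochs, batch 64 — lr/epochs/batch are
not dictated by the task and are exposed in `TrainConfig`. Initialization
is He-style uniform per layer from a single seeded generator; runs are
bit-reproducible per seed. Early stopping on a training-loss plateau
(patience 20, tol 1e-5) exists but is off by default so the epoch budget
is deterministic. Gradients are analytic backprop, verified against
central finite differences in the test suite.

No input normalization is applied by default — the evaluated pipeline fed
raw features, and min-max scaling is available behind a flag for
experimentation.

The **SNN** (single-network) baseline is the same code path with one
branch consuming all n features, dimensioned (2·d1, 2·d2) = (256, 64) so
its final representation width matches the dual model's concatenation.

## Baseline grid

Sixteen configurations: {LR, DT, RF, SVM-linear, SVM-poly, SVM-RBF, SNN,
DNN} × {plain, +CSL}. Non-neural learners come from scikit-learn with
library defaults, except RF fixed at 100 trees of depth ≤ 3; the fitted
models' parameters are recorded in the run report since "defaults" are
version-dependent. CSL for the non-neural learners is class weighting
with the same ratio {normal: 1, high-risk: m^n/m^d}. SVMs are ranked by
their decision function and thresholded at its sign; the probabilistic
models threshold `P(high risk)` at 0.5 (configurable). AUC and AP are
threshold-free.

## Evaluation

10-fold cross-validation on a seeded random (unstratified by default)
partition into folds whose sizes differ by at most one; every algorithm
in a run shares one fold assignment, so comparisons are paired by
construction. If an unstratified split yields a single-class test fold —
possible on small imbalanced samples — the split is redrawn with a
shifted seed and a warning is issued. Metrics per test fold: AUC (ties
count one half), average precision (recall-increment-weighted precision),
sensitivity and specificity. AUC/AP are computed by scikit-learn and
cross-checked in the tests against exhaustive pair-counting and
threshold-sweep references.

Comparisons against a reference algorithm (DNN+CSL by convention) are
one-sided paired t-tests across the 10 fold-wise values, alternative
"reference exceeds comparator"; pairing by fold is a choice — folds are
the natural blocking unit — and an unpaired variant would test the same
direction on fold means. Zero-variance differences are flagged degenerate
with p ∈ {0, 0.5, 1} by the sign of the mean difference.

## Synthetic data

No public version of the motivating dataset exists, so the generator is a
first-class module emulating its structure:

* 2299 records, 132 profile + 435 assessment columns; exactly 427
  high-risk labels placed uniformly at random;
* the 96 complete features all sit in the profile group (the real data's
  profile was ~73% complete while every questionnaire feature had gaps);
  the remaining 36 profile columns take the lowest nonzero missing-rate
  bins, the assessment columns the rest, with assessment rates floored at
  4.9%;
* each incomplete column's missing rate is drawn uniformly within its
  bin — (1–9%: 49), (10–19%: 22), (20–29%: 6), (30–39%: 97), (40–49%: 5),
  (50–59%: 152), (60–69%: 140) — and cells are masked MCAR at that rate
  (a column that randomly receives zero masked cells gets one forced, so
  the complete/incomplete census is exact). An optional MAR mode ramps
  the missing probability with a complete covariate's rank;
* signal: per group g ∈ {p, q}, a latent matrix
  `Z_g = s_g · y_signed · u_gᵀ + N(0, I)` (u_g a random unit direction,
  y_signed = ±1) maps to features through Gaussian loadings plus
  independent N(0, noise_sd²) noise. Each group therefore carries its own
  signal, and a model using both groups outranks one using either alone —
  the premise that motivates the dual design;
* heterogeneity: profile columns are rescaled by factors drawn
  log-uniformly over 1.5 decades with positive offsets, emulating raw
  bio-measurements of incommensurate units next to 0/1 items; the
  rescaling multiplies signal and noise together, leaving per-feature
  signal-to-noise untouched. Half the assessment columns (configurable)
  are binarized at their median to mimic yes/no items;
* default signal strength 0.6 per group was fixed by calibrating the
  default-structure dataset so that the cost-sensitive dual model scores
  in the low-to-mid 0.8 AUC range — the discrimination regime typical of
  questionnaire-free cognitive screening — rather than saturating near 1;
* `mmse_scores_from_labels` draws integer scores uniformly in [24, 30]
  for normal and [0, 23] for high-risk cases, so label derivation inverts
  the generator exactly.

What the generator does **not** emulate: real questionnaire item
semantics and inter-item correlation, informative missingness, cohort
drift over the ten collection years, or measurement error structure.
Passing the behavioral suites therefore shows the pipeline produces the
documented qualitative patterns under the assumed data model, not that it
attains any particular real-data operating point. One known divergence:
on this synthetic family the scale-invariant random forest can outrank
the raw-feature neural models, whereas the motivating study found the
dual network best overall; the qualitative contrasts under test (CSL
raises sensitivity at specificity's expense; plain RF is the degenerate
high-specificity screener; the dual model outranks the single network
under group heterogeneity) are the properties the generator is designed
to exhibit.

## Problem sizes in the checks

The structural checks run at the full 2299 × 567 size. The behavioral
suites run on scaled datasets that keep the full 567-column structure at
reduced record counts (600 for the cost-sensitivity contrast, 400 for the
dual-vs-single comparison) or on reduced-width configs (the no-signal
null), with 5 seeds each; these sizes are the package's own defaults for
its example experiments.

## Known limitations

* KNN imputation weighs all complete features equally in the distance;
  no per-feature weighting is provided.
* The cost ratio is fixed at the training class ratio; it is not tuned.
* Binary classification only; no multi-level MMSE severity output.
* The t-test treats fold metrics as exchangeable pairs; folds share
  training data, so p-values are approximate in the usual CV sense.
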