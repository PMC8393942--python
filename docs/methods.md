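# Methods

This note documents the statistical model behind `connpred`, the design of
the synthetic cohort generator, the numerical choices made where the
protocol left them open, and the limits of what the synthetic validation
shows.

## 1. The prediction protocol

The unit of analysis is a **sample table**: one row per (subject, block)
for a single condition, columns the Fisher-z connectivity values of all
upper-triangle ROI pairs in a fixed canonical order (row-major over the
retained-ROI ordering; the order is internal — all reported edges go
through the edge↔ROI-pair index map).

`ConnectomeRegression.fit()` runs, for each of `n_repeats` repeats
(default 50):

1. **Subject-wise split.** `round(train_frac · n_subjects)` subjects go to
   training (default 0.75 → 9 of 12); all blocks of a subject stay on one
   side. Splits are drawn without replacement from an RNG keyed by
   `(seed, repeat)` so any fold can be reproduced in isolation.
2. **Nested univariate selection.** Pearson correlation of every edge with
   the target, computed on training rows only; the `k_features` (default
   70) largest |r| are kept, ties broken by ascending edge index so the
   selection is a deterministic function of the training data.
   Zero-variance edges get r = 0.
3. **Linear ε-SVR.** `C = 1`, `ε = 0.1` on the z-scored target
   (training-fold mean/SD). The fitted model is stored as an explicit
   `(w, b)` pair; predictions are exactly `x·w + b`.
4. **Held-out prediction** of all test-subject blocks.

**Metrics.** The default (`pooling="pooled"`) concatenates all test
predictions across repeats: MSE is the mean squared residual (reported
both on the z-scored scale, where a signal-free predictor scores ≈ 1, and
back-transformed to squared years), and COR is the Pearson correlation of
pooled predictions with pooled truths. A per-fold-mean variant
(`pooling="fold_mean"`) is available because pooling conventions differ
across the literature; folds with undefined correlation (constant
predictions) are excluded from the fold-mean with a logged count. Folds
with a constant training target are skipped with a warning, never
silently.

**Permutation inference.** The exchange unit is the subject: a permutation
reassigns the subjects' target values among subjects, blocks inherit their
subject's permuted value, and the *entire* cross-validation (selection
included) is re-run. This preserves the within-subject dependence of block
rows; permuting rows independently would be anti-conservative.
`p = (1 + #{null at least as extreme}) / (n_perm + 1)` with "extreme"
being ≥ for COR and ≤ for MSE (compared on the standardized scale so
observed and null are commensurate); p is therefore bounded in
[1/(n_perm+1), 1]. A reduced `n_repeats` inside permutations is allowed
and logged. Bonferroni family size defaults to m = 4 (two targets × two
conditions per metric) and is configurable, since the appropriate family
depends on how many analyses a user runs.

**Confound controls.** Two complementary controls for the age–expertise
correlation:

* *Residualization* (`confound_mode="residualize"`): each edge is replaced
  by its residual from a univariate OLS on the confound, coefficients
  estimated on training rows only (per fold) and applied to all rows. A
  whole-sample variant exists behind `confound_on_train=False` but is off
  by default: estimating the residualization on all rows leaks held-out
  information and, on synthetic data, badly distorts the prediction.
  Note an intrinsic ceiling: with confound correlation ρ, residualized
  features can at best track the confound-partialled component of the
  target, so the achievable COR shrinks by a factor approaching
  √(1−ρ²) ≈ 0.73 at ρ = 0.68 even when the underlying couplings are
  perfectly disjoint. A modest COR drop under residualization is
  therefore expected, not evidence of confounding.
* *Selection overlap*: the correlation of the two targets' per-edge
  selection-frequency vectors (computed over all edges, zeros included).
  Disjoint relevant features ⇒ near-zero overlap ⇒ the predictions do not
  ride on the shared variance.

**Transfer.** `results.transfer(new_samples)` applies every fold's model
to a new cohort (same edge map enforced), averages the per-row predictions
across folds, and reports MSE and COR; constant targets yield an explicit
NaN COR with a flag rather than an exception.

## 2. The synthetic cohort generator

The generator reproduces the *statistical* structure the analysis assumes,
not images: no voxels, no registration, no tissue segmentation.

**Covariates.** Expertise (years of practice) is drawn from a normal
distribution left-truncated at zero whose latent parameters are
moment-matched (via the truncated-normal moment equations) so the
*observed* marginal has mean 16.41 and SD 7.69 years; age is generated
linearly in standardized expertise plus Gaussian noise to give mean 37.9,
SD 9.4 years and Pearson correlation 0.68 exactly in expectation. Pairs
violating 0 ≤ expertise < age are rejected and redrawn (probability
~10⁻³ at the default calibration, so the calibration survives). Novice
cohorts (10 subjects, age 33.0 ± 4.0) have expertise pinned to zero.
Years are the native unit throughout; practice hours are never needed
downstream.

**Parcellation.** 90 ROIs in 14 large-scale networks (sizes 7, 3, 5, 9,
2, 7, 6, 12, 4, 2, 6, 6, 10, 11), with synthetic per-subject grey-matter
coverage flags; by default 7 ROIs lack coverage in at least one subject,
so the retention rule (keep an ROI iff covered in *every* subject) leaves
83.

**Effect map.** Edge sets drawn without replacement among the
fully-covered ROIs' pairs: age-coupled edges apply in both conditions;
expertise-coupled edges are condition-specific except for an explicitly
configured shared subset; the age set is disjoint from all expertise
sets. Slopes have fixed magnitude (`slope_scale`, in Fisher-z units per
covariate SD) and independent random signs.

**Sessions.** For one subject/condition, the target correlation matrix
starts from a network-block base (within-network r = 0.35, between
r = 0.08), planted couplings are added on the Fisher-z scale
(`z ← z + slope · c_std`), and the result is mapped back through tanh and
projected to the nearest positive-semidefinite correlation matrix
(eigenvalue floor 10⁻⁶, then diagonal rescale). Block time series are
Gaussian draws from that matrix, smoothed by a variance-preserving AR(1)
(coefficient 0.3, mimicking BOLD autocorrelation), then contaminated:
every ROI loads linearly on two smooth random-walk nuisance channels
(white-matter and CSF "means") and six smooth random-walk motion
parameters (gain 0.7), and `n_spikes = 3` sustained translation steps of
0.7 mm per block produce exactly one FD > 0.5 mm volume each (placed
after the first five volumes so they survive the initial discard), with a
co-located high-amplitude artifact in the data. The contamination lies in
the span of the nuisance design on purpose: the cleaning stage has real
work to do and can in principle succeed, which the tests verify
(post-cleaning correlations are closer to ground truth than raw ones).

**Default effect regime.** Defaults are 70 age edges, 50 expertise edges
per condition (5 shared), slope 0.4. These were set during generator
design so that the planted structure is *recoverable* at the study's
size — 12 subjects, ~80 usable volumes per block after discard and
scrubbing, where a single-edge z estimate carries a standard error of
roughly 0.1–0.15. The reference findings this emulates (near-ceiling
prediction of both traits; selection frequencies almost perfectly
correlated across conditions for age, nearly uncorrelated for expertise)
imply exactly such a strongly-recoverable regime; with weak plants
(slope 0.15, 20 age edges) prediction still succeeds but noise edges
dilute the selection-frequency contrast. Block length is 88 volumes
(⌊360 s / 4.087 s⌋).

**Two caveats of the construction.** (i) The PSD projection is not
effect-preserving: at the strong default regime it attenuates the
realized edge couplings by ~25% relative to the nominal slope (they stay
linear and monotone, which is what recovery analyses use); at moderate
slopes the projection is a negligible perturbation and nominal slopes are
recovered within sampling error. (ii) The expertise < age constraint
makes exact covariate independence unattainable: at ρ = 0, rejection
induces a residual correlation of ≈ 0.08.

## 3. Introspection conventions

* **Selection frequency**: raw per-edge fold counts (no consensus
  restriction first), correlated across tasks/conditions over all edges
  including zeros.
* **Consensus weights**: within each fold the k selected weights are
  z-scored (putting folds on a common scale), then averaged per edge over
  the folds where it was selected; membership requires selection in
  ≥ 95% of folds (configurable).
* **Network matrix**: mean consensus weight per network pair
  (within-network on the diagonal), z-scored over non-empty cells; empty
  cells stay NaN. Symmetric by construction.
* **Node importance**: mean |consensus weight| over a node's incident
  consensus edges, reported both raw and standardized to mean 0, SD 1
  across touched nodes (a "mean 1, SD 0" normalization is not realizable;
  both versions preserve ranking). Untouched nodes are flagged zeros.
* **Group contrast**: blocks are averaged to one value per subject per
  edge before a two-sided Welch t-test, avoiding pseudo-replication from
  repeated blocks; the exchange/aggregation unit is the subject
  throughout the package.

## 4. Reproducibility and problem sizes

Every stochastic component draws from `numpy` Generators keyed by
explicit integer tuples — `(seed, subject, condition, block)` for the
simulator, `(seed, 7001, repeat)` for splits, `(seed, 7002, permutation,
repeat)` inside permutation tests — so identical seeds give bit-identical
datasets and any fold or permutation is reproducible in isolation
(subject keys use CRC32, not Python's randomized `hash`). Permutation
runs reuse the already-computed sample tables: targets change, features
do not.

The test suite exercises the full pipeline at the study's native size
(12 subjects, 83 ROIs, 3403 edges) with 20 cross-validation repeats, and
validates permutation calibration on 200 reduced null datasets (10
subjects × 2 blocks, 28 edges, 49 permutations each); the full protocol
(50 repeats, 1000 permutations) is the library default and is what
`connpred full` runs.

## 5. What the synthetic validation does and does not show

Passing tests demonstrate that the *pipeline* is correct: no train/test
leakage, calibrated permutation p-values, exact oracle agreement for
selection, pooling, scrubbing and aggregation, and faithful recovery of
planted linear edge–covariate couplings under realistic nuisance
contamination. They do not show that real meditation fMRI carries such
signals: the generator's effects are linear with homogeneous magnitude,
its noise is Gaussian with a single AR(1) scale, nuisance contamination
is exactly linear in the modeled regressors, and there is no scanner
drift structure, physiological aliasing, or inter-subject variability in
the base connectome beyond the planted couplings. Real-data performance
numbers therefore cannot be compared against the synthetic ones; only
the structural counts and cohort calibration carry over.
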