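# connpred

Connectome-based pattern regression: predicting continuous subject traits
(years of meditation practice, age) from block-wise functional-connectivity
matrices, together with a fully ground-truthed synthetic cohort generator.

## The problem

In small neuroimaging cohorts, multivariate pattern regression on
functional connectivity is easy to get subtly wrong: feature selection must
be nested inside the cross-validation, train/test splits must respect
subjects (not scan blocks), significance must come from permutation nulls
that shuffle at the subject level, and correlated covariates (here age and
meditation expertise, r ≈ 0.68) must be disentangled with explicit
confound controls. `connpred` implements that full protocol as a tested
library, and — because the original scanner data are not deposited —
pairs it with a generator that emulates the study's statistical structure
(12 practitioners × 2 meditation styles × 3 blocks of ~88 volumes at
TR 4.087 s, 90 ROIs in 14 large-scale networks, 83 retained after
grey-matter coverage screening) with *planted, known* edge–covariate
couplings, so every stage of the analysis is verifiable against ground
truth.

## The method

For each scan block, ROI time series are cleaned (initial-volume discard;
OLS removal of white-matter/CSF means, motion parameters and a linear
trend; zero-phase 0.009–0.08 Hz Butterworth band-pass; censoring of
volumes with framewise displacement FD > 0.5 mm), correlated pairwise
(Pearson), Fisher z-transformed (z = arctanh r), and vectorized over the
upper triangle — 83 ROIs give p(p−1)/2 = 3403 edge features per block,
36 samples per condition.

The regression protocol, repeated over R = 50 random subject-wise splits
(75% train / 25% test):

1. rank all edges by |Pearson r(edge, target)| **on training rows only**
   and keep the top k = 70;
2. fit a linear ε-insensitive support-vector regression (C = 1) on the
   selected training features, target z-scored with training statistics;
3. predict the held-out subjects' blocks.

Pooled over all repeats, the mean squared error (MSE, on the standardized
and on the raw-years scale) and the Pearson correlation of predictions
with truths (COR) summarize performance; significance comes from
subject-level permutation tests (n = 1000,
p = (1 + #{null ≥ observed}) / (n + 1), Bonferroni-adjustable), confound
robustness from per-fold residualization of the other covariate and from
the overlap of the two targets' selection frequencies, and
interpretability from consensus weights (edges selected in ≥ 95% of
folds, fold-z-scored and averaged) aggregated to networks and nodes.

## Worked example

```python
from connpred import (CohortConfig, generate_cohort, assemble_samples,
                      ConnectomeRegression)

cohort = generate_cohort(CohortConfig.meditators(seed=1))
fa = assemble_samples(cohort, "FA")           # clean + correlate + vectorize
res = ConnectomeRegression(fa, target="expertise",
                           n_repeats=20, seed=1).fit()
print(res.summary())
pt = res.permutation_test(n_perm=100, n_repeats=5)
print(f"permutation p (COR): {pt.p_cor:.4f}")
```

prints

```
Connectome Pattern Regression Results
=====================================================
Target:                     expertise
Condition:                  FA
Samples (subj x block):     36
Edges (features):           3403
Selected per fold (k):      70
SVR C / epsilon:            1.0 / 0.1
CV repeats x train frac:    20 x 0.75
Confound mode:              none
-----------------------------------------------------
MSE (standardized):         0.0583
MSE (target units^2):       4.0383
COR (pred vs true):         0.9740
=====================================================
permutation p (COR): 0.0099
```

Predicted expertise correlates 0.97 with the planted truth (the generator's
default regime plants strong effects), the standardized MSE is far below
the null value of ≈ 1, and no permutation reached the observed COR
(p = 1/101). Comparing which edges the selection picks across meditation
styles reproduces the study's dissociation on the same run: age-linked
selections agree across FA and OM (frequency correlation 0.83 here)
while expertise-linked selections do not (0.08), because the generator
plants condition-invariant age edges but condition-specific expertise
edges.

The same analysis is scriptable from the shell:

```bash
connpred simulate --preset meditators --seed 1 --out data/
connpred fit --data data/ --condition FA --target expertise \
         --seed 1 --n-repeats 20 --out fit/
connpred full --seed 1 --quick --out run/    # entire 2x2 grid + controls
```

## Layout

| module | contents |
| --- | --- |
| `connpred.simulate` | covariate sampler, parcellation, effect maps, session/cohort generator |
| `connpred.preprocess` | discard, nuisance regression, band-pass, FD, scrubbing, ROI retention |
| `connpred.connectome` | correlation matrices, Fisher z, edge vectorization, sample tables |
| `connpred.regression` | `ConnectomeRegression` / `ConnectomeRegressionResults`, permutation tests, confound controls, transfer |
| `connpred.introspection` | selection frequencies, consensus weights, network/node aggregation, group contrasts |
| `connpred.pipeline`, `connpred.cli` | full-study orchestration and the `connpred` command |

See `docs/methods.md` for the model, its assumptions, and the numerical
choices.
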