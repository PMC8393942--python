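"""Connectome pattern regression.

The predictive core: univariate correlation-based feature selection nested
inside repeated subject-wise cross-validation of a linear epsilon-insensitive
support-vector regression (SVR), with permutation-test significance,
confound residualization and cross-group transfer.

The public surface follows the model/results convention: build a
:class:`ConnectomeRegression` from a :class:`~connpred.connectome.SampleTable`
and a target name, call :meth:`~ConnectomeRegression.fit`, and work with the
returned :class:`ConnectomeRegressionResults` (pooled metrics, per-fold
selections and weights, ``summary()``, ``permutation_test()``,
``transfer()``).

Design notes
------------
* Subjects — not rows — are the cross-validation and permutation unit: all
  blocks of a subject stay on one side of every split, and permutations
  shuffle targets across subjects with blocks inheriting their subject's
  permuted value.  This preserves the within-subject dependence of the
  block rows.
* Targets are z-scored with training-fold statistics.  The pooled mean
  squared error is reported both on that standardized scale (``mse``) and
  back-transformed to squared years (``mse_years``); the pooled COR is the
  Pearson correlation of predictions and truths over all test rows of all
  repeats (a per-fold-mean alternative is available via ``pooling``).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from connpred.connectome import SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectomeRegression",
    "ConnectomeRegressionResults",
    "FoldResult",
    "PermutationResult",
    "RegressionConfig",
    "TransferResult",
    "bonferroni",
    "cross_validate",
    "fit_svr",
    "pearson_feature_correlation",
    "residualize_confound",
    "select_features",
    "split_subjects",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RegressionConfig:
    """Settings of the cross-validated pattern regression.

    k_features : number of edges kept by univariate selection (default 70)
    c_reg : SVR regularization constant C (default 1)
    epsilon_tube : epsilon-insensitive tube half-width on the z-scored
        target (default 0.1, the common solver default)
    n_repeats : number of random subject-wise splits (default 50)
    train_frac : fraction of subjects in the training side (default 0.75)
    n_perm : permutations for the null distribution (default 1000)
    target : "age" or "expertise"
    confound_mode : "none" or "residualize" (remove the confound covariate
        from every edge before selection/fitting)
    confound_on_train : estimate residualization coefficients on training
        rows only (default) rather than on the whole sample
    pooling : "pooled" (metrics over all test predictions) or "fold_mean"
    bonferroni_m : multiple-comparison family size (default 4: two targets
        by two conditions per metric)
    """

    target: str = "expertise"
    k_features: int = 70
    c_reg: float = 1.0
    epsilon_tube: float = 0.1
    n_repeats: int = 50
    train_frac: float = 0.75
    n_perm: int = 1000
    seed: int = 0
    confound: str | None = None
    confound_mode: str = "none"
    confound_on_train: bool = True
    pooling: str = "pooled"
    bonferroni_m: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.train_frac < 1.0):
            raise ValueError("train_frac must lie in (0, 1)")
        if self.k_features < 1:
            raise ValueError("k_features must be positive")
        if self.confound_mode not in ("none", "residualize"):
            raise ValueError("confound_mode must be 'none' or 'residualize'")
        if self.pooling not in ("pooled", "fold_mean"):
            raise ValueError("pooling must be 'pooled' or 'fold_mean'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def pearson_feature_correlation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every column of ``x`` with ``y`` (vectorized).

    Zero-variance columns get r = 0 (they carry no information for
    ranking)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    if sy == 0:
        raise ValueError("target has zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return r


def select_features(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k features most correlated (in |r|) with the target.

    Ties are broken by ascending feature index, making the selection
    deterministic.
    """
    if k > x.shape[1]:
        raise ValueError(f"k={k} exceeds the {x.shape[1]} available features")
    absr = np.abs(pearson_feature_correlation(x, y))
    order = np.lexsort((np.arange(absr.size), -absr))
    return np.sort(order[:k])


def fit_svr(x_train: np.ndarray, y_train: np.ndarray, c_reg: float = 1.0,
            epsilon_tube: float = 0.1) -> tuple[np.ndarray, float]:
    """Linear epsilon-insensitive SVR; returns (weights, intercept) so that
    predictions are exactly ``x @ w + b``."""
    if np.unique(y_train).size < 2:
        raise ValueError("need at least 2 distinct training targets")
    model = SVR(kernel="linear", C=c_reg, epsilon=epsilon_tube)
    model.fit(x_train, y_train)
    return model.coef_.ravel().copy(), float(model.intercept_[0])


def split_subjects(subject_ids, train_frac: float, seed: int,
                   repeat_index: int,
                   key: tuple[int, ...] = ()) -> tuple[list[str], list[str]]:
    """Random subject-wise train/test split for one repeat.

    n_train = round(train_frac * n_subjects); sampling without replacement;
    the same (seed, repeat_index) always gives the same split.
    """
    subject_ids = list(subject_ids)
    n = len(subject_ids)
    if n < 4:
        raise ValueError("need at least 4 subjects to split")
    n_train = int(round(train_frac * n))
    if n_train in (0, n):
        raise ValueError(f"train_frac {train_frac} leaves an empty side "
                         f"for {n} subjects")
    rng = np.random.default_rng([int(seed), 7001, *key, int(repeat_index)])
    perm = rng.permutation(n)
    train = [subject_ids[i] for i in sorted(perm[:n_train])]
    test = [subject_ids[i] for i in sorted(perm[n_train:])]
    return train, test


def residualize_confound(samples: SampleTable, confound: np.ndarray,
                         fit_rows: np.ndarray) -> SampleTable:
    """Remove a covariate's linear contribution from every edge column.

    Per-edge univariate OLS (intercept + confound) is estimated on
    ``fit_rows`` only and applied to all rows, so held-out rows never
    influence the coefficients.
    """
    confound = np.asarray(confound, dtype=float)
    c_fit = confound[fit_rows]
    if c_fit.std() == 0:
        raise ValueError("confound has zero variance on the fitting rows")
    cc = c_fit - c_fit.mean()
    x_fit = samples.features[fit_rows]
    beta = cc @ (x_fit - x_fit.mean(axis=0)) / (cc ** 2).sum()
    alpha = x_fit.mean(axis=0) - beta * c_fit.mean()
    resid = samples.features - (alpha[None, :] + np.outer(confound, beta))
    return SampleTable(features=resid, meta=samples.meta.copy(),
                       edges=samples.edges)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: m * p, capped at 1."""
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# Fold bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """One repeat of the cross-validation."""

    repeat_index: int
    train_subjects: list[str]
    test_subjects: list[str]
    selected: np.ndarray          # edge indices, ascending
    weights: np.ndarray           # over selected edges, z-scored-target scale
    intercept: float
    y_mean: float                 # training-target scaler
    y_sd: float
    test_rows: np.ndarray         # row indices into the sample table
    pred_std: np.ndarray          # predictions on the z-scored scale
    pred: np.ndarray              # predictions in target units (years)

    def predict(self, features: np.ndarray,
                in_target_units: bool = True) -> np.ndarray:
        z = features[:, self.selected] @ self.weights + self.intercept
        return self.y_mean + self.y_sd * z if in_target_units else z


def _pearson_or_nan(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class ConnectomeRegression:
    """Cross-validated connectome pattern regression model.

    Parameters
    ----------
    samples : SampleTable
        Single-condition edge-feature table (rows = subject x block).
    target : str
        Column of ``samples.meta`` to predict ("expertise" or "age").
    config : RegressionConfig, optional
        Full settings object; keyword overrides are applied on top.
    **overrides
        Any :class:`RegressionConfig` field, e.g. ``n_repeats=20, seed=7``.

    Examples
    --------
    >>> model = ConnectomeRegression(samples, target="expertise", seed=0)
    >>> res = model.fit()
    >>> res.cor, res.mse
    """

    def __init__(self, samples: SampleTable, target: str = "expertise",
                 config: RegressionConfig | None = None, **overrides):
        if target not in samples.meta.columns:
            raise ValueError(f"target {target!r} not in sample metadata")
        base = config.to_dict() if config is not None else {}
        base["target"] = target
        base.update(overrides)
        self.config = RegressionConfig(**base)
        if self.config.k_features > samples.n_edges:
            raise ValueError("k_features exceeds the number of edges")
        self.samples = samples
        self.target = target

    # -- internals ---------------------------------------------------------

    def _prepared(self, y_by_subject: dict[str, float] | None,
                  train_subjects: list[str]) -> tuple[SampleTable, np.ndarray]:
        """Per-fold feature table (confound-residualized if configured) and
        target vector (optionally subject-permuted)."""
        samples = self.samples
        if y_by_subject is None:
            y = samples.target(self.target)
        else:
            y = samples.meta["subject_id"].map(y_by_subject).to_numpy(float)
        if self.config.confound_mode == "residualize":
            conf = samples.target(self.config.confound or
                                  ("expertise" if self.target == "age"
                                   else "age"))
            fit_rows = (samples.rows_for(train_subjects)
                        if self.config.confound_on_train
                        else np.arange(samples.n_samples))
            samples = residualize_confound(samples, conf, fit_rows)
        return samples, y

    def _run_cv(self, seed_key: tuple[int, ...] = (),
                n_repeats: int | None = None,
                y_by_subject: dict[str, float] | None = None
                ) -> list[FoldResult]:
        cfg = self.config
        n_repeats = cfg.n_repeats if n_repeats is None else n_repeats
        subjects = self.samples.subject_ids
        folds: list[FoldResult] = []
        for rep in range(n_repeats):
            train_s, test_s = split_subjects(subjects, cfg.train_frac,
                                             cfg.seed, rep, key=seed_key)
            samples, y = self._prepared(y_by_subject, train_s)
            tr = samples.rows_for(train_s)
            te = samples.rows_for(test_s)
            y_tr = y[tr]
            if np.unique(y_tr).size < 2:
                logger.warning("repeat %d: constant training target, "
                               "fold skipped", rep)
                continue
            mu, sd = float(y_tr.mean()), float(y_tr.std())
            yz_tr = (y_tr - mu) / sd
            sel = select_features(samples.features[tr], y_tr, cfg.k_features)
            w, b = fit_svr(samples.features[tr][:, sel], yz_tr,
                           cfg.c_reg, cfg.epsilon_tube)
            pred_std = samples.features[te][:, sel] @ w + b
            folds.append(FoldResult(
                repeat_index=rep, train_subjects=train_s, test_subjects=test_s,
                selected=sel, weights=w, intercept=b, y_mean=mu, y_sd=sd,
                test_rows=te, pred_std=pred_std, pred=mu + sd * pred_std))
        if not folds:
            raise RuntimeError("every cross-validation fold was degenerate")
        return folds

    def _metrics(self, folds: list[FoldResult],
                 y: np.ndarray) -> tuple[float, float, float]:
        """(mse_std, mse_years, cor) under the configured pooling rule."""
        if self.config.pooling == "pooled":
            pred = np.concatenate([f.pred for f in folds])
            pred_std = np.concatenate([f.pred_std for f in folds])
            truth = np.concatenate([y[f.test_rows] for f in folds])
            truth_std = np.concatenate(
                [(y[f.test_rows] - f.y_mean) / f.y_sd for f in folds])
            mse_std = float(np.mean((pred_std - truth_std) ** 2))
            mse = float(np.mean((pred - truth) ** 2))
            cor = _pearson_or_nan(pred, truth)
            return mse_std, mse, cor
        mses, mses_y, cors = [], [], []
        for f in folds:
            t = y[f.test_rows]
            mses.append(np.mean((f.pred_std - (t - f.y_mean) / f.y_sd) ** 2))
            mses_y.append(np.mean((f.pred - t) ** 2))
            c = _pearson_or_nan(f.pred, t)
            if not np.isnan(c):
                cors.append(c)
        return float(np.mean(mses)), float(np.mean(mses_y)), \
            float(np.mean(cors)) if cors else float("nan")

    # -- public API --------------------------------------------------------

    def fit(self) -> "ConnectomeRegressionResults":
        """Run the repeated nested cross-validation."""
        folds = self._run_cv()
        y = self.samples.target(self.target)
        mse_std, mse_years, cor = self._metrics(folds, y)
        return ConnectomeRegressionResults(
            model=self, folds=folds, mse=mse_std, mse_years=mse_years,
            cor=cor)


def cross_validate(samples: SampleTable,
                   config: RegressionConfig) -> "ConnectomeRegressionResults":
    """Functional entry point: fit a :class:`ConnectomeRegression`."""
    return ConnectomeRegression(samples, target=config.target,
                                config=config).fit()


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Null distributions and permutation p-values for MSE and COR."""

    null_mse: np.ndarray
    null_cor: np.ndarray
    observed_mse: float
    observed_cor: float
    p_mse: float
    p_cor: float
    p_mse_bonferroni: float
    p_cor_bonferroni: float
    n_perm: int
    m: int


@dataclass
class TransferResult:
    """Metrics of a model applied to a new cohort (fold-averaged
    predictions).  ``cor`` is NaN with ``cor_undefined`` set when the new
    targets are constant."""

    mse: float
    mse_std: float
    cor: float
    cor_undefined: bool
    predictions: pd.DataFrame


@dataclass
class ConnectomeRegressionResults:
    """Estimates and diagnostics of a fitted connectome pattern regression.

    Attributes
    ----------
    folds : per-repeat selections, weights and test predictions
    mse : pooled mean squared error on the z-scored target scale
    mse_years : pooled mean squared error in squared target units
    cor : pooled Pearson correlation of predictions and truths
    """

    model: ConnectomeRegression
    folds: list[FoldResult]
    mse: float
    mse_years: float
    cor: float

    @property
    def config(self) -> RegressionConfig:
        return self.model.config

    @property
    def samples(self) -> SampleTable:
        return self.model.samples

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def predictions_table(self) -> pd.DataFrame:
        """All test predictions, one row per (repeat, test sample)."""
        y = self.samples.target(self.model.target)
        rows = []
        for f in self.folds:
            for r, pz, p in zip(f.test_rows, f.pred_std, f.pred):
                rows.append({"repeat": f.repeat_index, "row": int(r),
                             "subject_id": self.samples.meta.loc[r, "subject_id"],
                             "true": y[r], "pred": p, "pred_std": pz})
        return pd.DataFrame(rows)

    # -- inference ---------------------------------------------------------

    def permutation_test(self, n_perm: int | None = None,
                         n_repeats: int | None = None,
                         m: int | None = None) -> PermutationResult:
        """Subject-level permutation null for the pooled MSE and COR.

        Targets are shuffled across subjects (blocks inherit their
        subject's permuted value) and the full cross-validation is re-run
        per permutation; ``n_repeats`` may be reduced relative to the
        observed fit (logged).  p = (1 + #{null at least as extreme}) /
        (n_perm + 1), where "extreme" means >= for COR and <= for MSE.
        MSE comparisons use the standardized scale so observed and null
        are commensurate.
        """
        cfg = self.model.config
        n_perm = cfg.n_perm if n_perm is None else n_perm
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        m = cfg.bonferroni_m if m is None else m
        if n_repeats is not None and n_repeats != cfg.n_repeats:
            logger.info("permutation test with reduced n_repeats=%d "
                        "(observed fit used %d)", n_repeats, cfg.n_repeats)
        subjects = self.samples.subject_ids
        y_subj = self.samples.meta.drop_duplicates("subject_id") \
            .set_index("subject_id")[self.model.target]
        null_mse = np.empty(n_perm)
        null_cor = np.empty(n_perm)
        y_all = self.samples.target(self.model.target)
        for p_i in range(n_perm):
            rng = np.random.default_rng([cfg.seed, 7002, p_i])
            perm = rng.permutation(len(subjects))
            mapping = {subjects[i]: float(y_subj.loc[subjects[perm[i]]])
                       for i in range(len(subjects))}
            folds = self.model._run_cv(seed_key=(7002, p_i),
                                       n_repeats=n_repeats,
                                       y_by_subject=mapping)
            y_perm = self.samples.meta["subject_id"].map(mapping) \
                .to_numpy(float)
            mse_std, _, cor = self.model._metrics(folds, y_perm)
            null_mse[p_i] = mse_std
            null_cor[p_i] = cor
        obs_cor = self.cor
        p_cor = (1 + int(np.sum(null_cor >= obs_cor))) / (n_perm + 1)
        p_mse = (1 + int(np.sum(null_mse <= self.mse))) / (n_perm + 1)
        return PermutationResult(
            null_mse=null_mse, null_cor=null_cor, observed_mse=self.mse,
            observed_cor=obs_cor, p_mse=p_mse, p_cor=p_cor,
            p_mse_bonferroni=bonferroni(p_mse, m),
            p_cor_bonferroni=bonferroni(p_cor, m), n_perm=n_perm, m=m)

    def transfer(self, new_samples: SampleTable,
                 target: str | None = None) -> TransferResult:
        """Apply every fold's model to a new cohort and score the
        fold-averaged per-row predictions."""
        if new_samples.edges != self.samples.edges:
            raise ValueError("edge index maps differ between cohorts")
        target = target or self.model.target
        y = new_samples.target(target)
        preds = np.mean([f.predict(new_samples.features) for f in self.folds],
                        axis=0)
        preds_std = np.mean([f.predict(new_samples.features, False)
                             for f in self.folds], axis=0)
        sd_ref = float(np.mean([f.y_sd for f in self.folds]))
        mu_ref = float(np.mean([f.y_mean for f in self.folds]))
        mse = float(np.mean((preds - y) ** 2))
        mse_std = float(np.mean((preds_std - (y - mu_ref) / sd_ref) ** 2))
        undefined = bool(np.std(y) == 0 or np.std(preds) == 0)
        if undefined:
            warnings.warn("COR undefined (constant targets or predictions); "
                          "returning NaN", RuntimeWarning, stacklevel=2)
        cor = float("nan") if undefined else float(np.corrcoef(preds, y)[0, 1])
        table = pd.DataFrame({
            "subject_id": new_samples.meta["subject_id"],
            "true": y, "pred": preds})
        return TransferResult(mse=mse, mse_std=mse_std, cor=cor,
                              cor_undefined=undefined, predictions=table)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        cfg = self.config
        cond = sorted(set(self.samples.meta["condition"]))
        lines = [
            "Connectome Pattern Regression Results",
            "=" * 53,
            f"{'Target:':<28}{self.model.target}",
            f"{'Condition:':<28}{', '.join(cond)}",
            f"{'Samples (subj x block):':<28}{self.samples.n_samples}",
            f"{'Edges (features):':<28}{self.samples.n_edges}",
            f"{'Selected per fold (k):':<28}{cfg.k_features}",
            f"{'SVR C / epsilon:':<28}{cfg.c_reg} / {cfg.epsilon_tube}",
            f"{'CV repeats x train frac:':<28}"
            f"{self.n_folds} x {cfg.train_frac}",
            f"{'Confound mode:':<28}{cfg.confound_mode}",
            "-" * 53,
            f"{'MSE (standardized):':<28}{self.mse:.4f}",
            f"{'MSE (target units^2):':<28}{self.mse_years:.4f}",
            f"{'COR (pred vs true):':<28}{self.cor:.4f}",
            "=" * 53,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<ConnectomeRegressionResults target={self.model.target!r} "
                f"folds={self.n_folds} mse={self.mse:.3f} cor={self.cor:.3f}>")
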