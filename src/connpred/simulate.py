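"""Synthetic cohort generator with planted covariate-coupled connectivity.

Emulates the statistical structure of a block-design meditation fMRI study:
a small cohort of long-term practitioners scanned during two meditation
styles — focused attention (FA) and open monitoring (OM) — in three blocks
per style, with region-of-interest (ROI) time series drawn from a
ground-truth correlation matrix.  Selected edges (unordered ROI pairs) carry
linear couplings to a subject covariate: age-coupled edges are shared by the
two conditions, expertise-coupled edges are condition-specific except for an
explicitly configured shared subset.  White-matter/CSF drifts, motion
contamination and high-motion spike volumes give the preprocessing stage
real work; the full ground truth (effect map, per-session correlation
matrices, motion traces) is retained for verification.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NETWORKS",
    "CohortConfig",
    "Cohort",
    "EffectMap",
    "Parcellation",
    "SimulatedSession",
    "TimeSeriesBlock",
    "build_effect_map",
    "default_parcellation",
    "generate_cohort",
    "sample_covariates",
    "simulate_session",
]

#: 14 large-scale networks of the default 90-ROI functional parcellation,
#: with the number of ROIs each contributes (sums to 90).
NETWORKS: tuple[tuple[str, int], ...] = (
    ("Anterior Salience", 7),
    ("Auditory", 3),
    ("Basal Ganglia", 5),
    ("Dorsal DMN", 9),
    ("Higher Visual", 2),
    ("Language", 7),
    ("LECN", 6),
    ("Posterior Salience", 12),
    ("Precuneus", 4),
    ("Primary Visual", 2),
    ("RECN", 6),
    ("Sensorimotor", 6),
    ("Ventral DMN", 10),
    ("Visuospatial", 11),
)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _truncnorm_latent(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Latent (mu, sigma) of a normal left-truncated at 0 whose truncated
    distribution has the requested mean and standard deviation."""

    def eqs(x):
        mu, sig = x
        if sig <= 0:
            return [1e6, 1e6]
        a = (0.0 - mu) / sig
        d = stats.truncnorm(a, np.inf, loc=mu, scale=sig)
        return [d.mean() - target_mean, d.std() - target_sd]

    sol = optimize.root(eqs, x0=[target_mean, target_sd])
    if not sol.success:  # pragma: no cover - well-posed for realistic moments
        raise RuntimeError("truncated-normal moment matching failed to converge")
    return float(sol.x[0]), float(sol.x[1])


def sample_covariates(
    n_subjects: int,
    age_mean: float = 37.9,
    age_sd: float = 9.4,
    exp_mean: float = 16.41,
    exp_sd: float = 7.69,
    rho: float = 0.68,
    seed: int = 0,
    group: str = "meditator",
) -> pd.DataFrame:
    """Draw correlated (age, expertise) covariate pairs for a cohort.

    Expertise (years of practice) is sampled from a normal distribution
    left-truncated at zero whose latent parameters are moment-matched so the
    *truncated* marginal has mean ``exp_mean`` and SD ``exp_sd``.  Age is
    then generated linearly in standardized expertise plus Gaussian noise,
    which yields the requested marginal moments and Pearson correlation
    exactly in expectation.  Pairs violating ``0 <= expertise < age`` are
    resampled (rejection probability ~1e-3 at default calibration).

    Parameters
    ----------
    n_subjects : number of subjects (>= 2).
    age_mean, age_sd : age marginal moments in years.
    exp_mean, exp_sd : expertise marginal moments in years.
    rho : target age-expertise Pearson correlation, in (-1, 1).
    seed : RNG seed; identical seeds give identical tables.
    group : "meditator" or "novice"; novices get expertise 0 and only the
        age marginal is sampled.

    Returns
    -------
    DataFrame with columns subject_id, age, expertise, group.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if not (-1.0 < rho < 1.0):
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    if age_sd <= 0 or exp_sd <= 0:
        raise ValueError("standard deviations must be positive")
    if group not in ("meditator", "novice"):
        raise ValueError(f"unknown group {group!r}")

    rng = np.random.default_rng([int(seed), 101])

    if group == "novice":
        age = np.empty(0)
        while age.size < n_subjects:
            draw = rng.normal(age_mean, age_sd, size=2 * n_subjects)
            age = np.concatenate([age, draw[draw > 0]])
        age = age[:n_subjects]
        expertise = np.zeros(n_subjects)
    else:
        mu, sig = _truncnorm_latent(exp_mean, exp_sd)
        a = (0.0 - mu) / sig
        age_list: list[float] = []
        exp_list: list[float] = []
        while len(age_list) < n_subjects:
            m = max(2 * (n_subjects - len(age_list)), 16)
            e = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sig, size=m,
                                    random_state=rng)
            z = (e - exp_mean) / exp_sd
            ag = age_mean + rho * age_sd * z \
                + age_sd * np.sqrt(1.0 - rho ** 2) * rng.standard_normal(m)
            ok = (ag > e) & (ag > 0) & (e > 0)
            age_list.extend(ag[ok])
            exp_list.extend(e[ok])
        age = np.asarray(age_list[:n_subjects])
        expertise = np.asarray(exp_list[:n_subjects])

    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:02d}" for i in range(n_subjects)],
            "age": age,
            "expertise": expertise,
            "group": group,
        }
    )


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

@dataclass
class Parcellation:
    """ROI table (roi_id, roi_name, network) plus per-subject grey-matter
    coverage flags (True = ROI intersects grey matter in that subject)."""

    table: pd.DataFrame
    coverage: pd.DataFrame  # index: subject_id, columns: roi_id, bool

    def __post_init__(self) -> None:
        if not set(self.table["roi_id"]) == set(self.coverage.columns):
            raise ValueError("coverage columns must match parcellation roi_ids")

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        return list(dict.fromkeys(self.table["network"]))

    def network_of(self) -> pd.Series:
        """ROI id -> network label."""
        return self.table.set_index("roi_id")["network"]


def _abbrev(name: str) -> str:
    return "".join(w[0] if w.islower() else w[:3] for w in name.split())


def default_parcellation(
    subject_ids: list[str],
    n_uncovered: int = 7,
    seed: int = 0,
) -> Parcellation:
    """Build the default 90-ROI / 14-network parcellation with synthetic
    coverage flags.

    ``n_uncovered`` ROIs are marked as missing grey-matter intersection in at
    least one (randomly chosen) subject, so the retention rule applied later
    keeps ``90 - n_uncovered`` ROIs.
    """
    rows = []
    rid = 0
    for net, size in NETWORKS:
        for k in range(size):
            rows.append({"roi_id": rid, "roi_name": f"{_abbrev(net)}_{k + 1:02d}",
                         "network": net})
            rid += 1
    table = pd.DataFrame(rows)

    rng = np.random.default_rng([int(seed), 202])
    cov = pd.DataFrame(True, index=list(subject_ids), columns=table["roi_id"])
    if n_uncovered > 0:
        dropped = rng.choice(table["roi_id"].to_numpy(), size=n_uncovered,
                             replace=False)
        for r in dropped:
            n_bad = int(rng.integers(1, max(2, len(subject_ids) // 3 + 1)))
            bad = rng.choice(len(subject_ids), size=n_bad, replace=False)
            cov.iloc[bad, cov.columns.get_loc(r)] = False
    return Parcellation(table=table, coverage=cov)


# ---------------------------------------------------------------------------
# Effect map
# ---------------------------------------------------------------------------

@dataclass
class EffectMap:
    """Planted linear couplings between edges and covariates.

    One row per (edge, target): columns roi_i, roi_j (roi_i < roi_j),
    target in {age, expertise}, condition in {FA, OM, both}, slope in
    Fisher-z units per covariate standard deviation.  Age entries always
    have condition "both"; the age edge set is disjoint from every
    expertise edge set, and the FA/OM expertise sets are disjoint except
    for rows with condition "both".
    """

    entries: pd.DataFrame

    def edges(self, target: str, condition: str) -> pd.DataFrame:
        """Rows applying to ``condition`` ('FA' or 'OM') for ``target``."""
        e = self.entries
        m = (e["target"] == target) & e["condition"].isin([condition, "both"])
        return e[m]

    def edge_set(self, target: str, condition: str) -> set[tuple[int, int]]:
        sub = self.edges(target, condition)
        return set(zip(sub["roi_i"], sub["roi_j"]))


def build_effect_map(
    parcellation: Parcellation | list[int],
    n_age_edges: int = 70,
    n_exp_edges_per_condition: int = 50,
    n_shared_exp_edges: int = 5,
    slope_scale: float = 0.4,
    seed: int = 0,
    rois: list[int] | None = None,
) -> EffectMap:
    """Sample disjoint planted edge sets and attach random-sign slopes.

    Edges are drawn without replacement from all unordered pairs of the
    given ROIs (by default the ROIs covered in every subject, so planted
    edges survive the retention rule).  The age set is disjoint from every
    expertise set; the FA-only and OM-only expertise sets are disjoint from
    each other and from the shared subset.  Slopes have magnitude
    ``slope_scale`` and independent random signs.
    """
    if isinstance(parcellation, Parcellation):
        if rois is None:
            covered = parcellation.coverage.all(axis=0)
            rois = [int(r) for r in covered.index[covered]]
    else:
        rois = [int(r) for r in parcellation]
    if n_shared_exp_edges > n_exp_edges_per_condition:
        raise ValueError("shared expertise edges cannot exceed the per-condition count")
    p = len(rois)
    n_pairs = p * (p - 1) // 2
    # unique edges needed: age + shared + 2 * (per-condition - shared)
    n_needed = n_age_edges + n_shared_exp_edges \
        + 2 * (n_exp_edges_per_condition - n_shared_exp_edges)
    if n_needed > n_pairs:
        raise ValueError(
            f"requested {n_needed} distinct edges but only {n_pairs} pairs exist"
        )

    rng = np.random.default_rng([int(seed), 303])
    iu = np.triu_indices(p, k=1)
    order = rng.permutation(n_pairs)
    picked = [(rois[iu[0][k]], rois[iu[1][k]]) for k in order[:n_needed]]

    n_only = n_exp_edges_per_condition - n_shared_exp_edges
    cursor = 0
    groups = []
    for target, condition, count in (
        ("age", "both", n_age_edges),
        ("expertise", "both", n_shared_exp_edges),
        ("expertise", "FA", n_only),
        ("expertise", "OM", n_only),
    ):
        for i, j in picked[cursor:cursor + count]:
            groups.append({"roi_i": i, "roi_j": j, "target": target,
                           "condition": condition,
                           "slope": float(slope_scale * rng.choice([-1.0, 1.0]))})
        cursor += count
    return EffectMap(entries=pd.DataFrame(
        groups, columns=["roi_i", "roi_j", "target", "condition", "slope"]))


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesBlock:
    """One acquisition block: ROI time series with nuisance/motion sidecars.

    data : (volumes, n_rois) array of ROI signals
    nuisance : (volumes, 2) array, columns [white-matter mean, CSF mean]
    motion : (volumes, 6) array, 3 translations (mm) then 3 rotations (rad)
    """

    data: np.ndarray
    tr: float
    subject_id: str
    condition: str
    block_index: int
    roi_ids: np.ndarray
    nuisance: np.ndarray
    motion: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (volumes x ROIs)")
        if np.isnan(self.data).any():
            raise ValueError("time series contains missing values")
        for name in ("nuisance", "motion"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape[0] != self.n_volumes:
                raise ValueError(f"{name} has {arr.shape[0]} volumes, "
                                 f"data has {self.n_volumes}")
            setattr(self, name, arr)
        self.roi_ids = np.asarray(self.roi_ids)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def replace(self, **kw) -> "TimeSeriesBlock":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulatedSession:
    """All blocks of one (subject, condition) with their shared ground truth."""

    subject_id: str
    condition: str
    blocks: list[TimeSeriesBlock]
    ground_truth_r: np.ndarray  # post-projection correlation matrix
    roi_ids: np.ndarray


def _base_correlation(networks: np.ndarray, base_within: float,
                      base_between: float) -> np.ndarray:
    same = networks[:, None] == networks[None, :]
    r = np.where(same, base_within, base_between).astype(float)
    np.fill_diagonal(r, 1.0)
    return r


def _nearest_psd_correlation(r: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``eig_floor`` and rescale back to unit diagonal."""
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    if w.min() >= eig_floor:
        return r
    w = np.clip(w, eig_floor, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _smooth_walk(rng: np.random.Generator, n: int, smooth: int = 5) -> np.ndarray:
    """Standardized smooth random walk (slow drift)."""
    steps = rng.standard_normal(n + smooth)
    walk = np.cumsum(steps)
    kernel = np.ones(smooth) / smooth
    walk = np.convolve(walk, kernel, mode="valid")[:n]
    walk = walk - walk.mean()
    sd = walk.std()
    return walk / sd if sd > 0 else walk


def ground_truth_matrix(
    covariates: pd.Series,
    effect_map: EffectMap,
    condition: str,
    roi_ids: np.ndarray,
    networks: np.ndarray,
    base_within: float,
    base_between: float,
    covariate_norms: dict[str, tuple[float, float]],
    clip: float = 0.99,
) -> np.ndarray:
    """Target correlation matrix for one subject/condition before sampling.

    Planted couplings are added on the Fisher-z scale: for each applicable
    effect-map entry the edge's z value is shifted by slope times the
    subject's standardized covariate.  The result is mapped back through
    tanh, clipped to (-clip, clip) off-diagonal, and projected to the
    nearest positive-semidefinite correlation matrix.
    """
    r = _base_correlation(networks, base_within, base_between)
    z = np.arctanh(np.clip(r - np.eye(len(r)), -clip, clip))
    pos = {int(roi): k for k, roi in enumerate(roi_ids)}
    for target in ("age", "expertise"):
        mean, sd = covariate_norms[target]
        c_std = (float(covariates[target]) - mean) / sd
        for _, row in effect_map.edges(target, condition).iterrows():
            i, j = pos.get(int(row["roi_i"])), pos.get(int(row["roi_j"]))
            if i is None or j is None:
                continue
            z[i, j] += row["slope"] * c_std
            z[j, i] = z[i, j]
    r_target = np.tanh(z)
    np.fill_diagonal(r_target, 1.0)
    r_target = np.clip(r_target, -clip, clip)
    np.fill_diagonal(r_target, 1.0)
    return _nearest_psd_correlation(r_target)


def simulate_session(
    covariates: pd.Series,
    effect_map: EffectMap,
    parcellation: Parcellation,
    condition: str,
    n_volumes: int = 88,
    tr: float = 4.087,
    base_within: float = 0.35,
    base_between: float = 0.08,
    ar_coef: float = 0.3,
    nuisance_gain: float = 0.7,
    n_spikes: int = 3,
    n_blocks: int = 3,
    seed: int = 0,
    covariate_norms: dict[str, tuple[float, float]] | None = None,
    expertise_coupling: bool = True,
) -> SimulatedSession:
    """Simulate all blocks of one condition for one subject.

    The block time series are Gaussian draws from the subject's ground-truth
    correlation matrix, AR(1)-smoothed (variance-preserving), then
    contaminated with white-matter/CSF drifts and motion-derived signals
    scaled by ``nuisance_gain``, plus ``n_spikes`` high-amplitude volumes
    co-located with motion steps whose framewise displacement exceeds
    0.5 mm.  Spikes are placed after the first five volumes so they survive
    the initial-volume discard.
    """
    if not (0 <= base_between < 1 and 0 <= base_within < 1):
        raise ValueError("base correlations must lie in [0, 1)")
    if not abs(ar_coef) < 1:
        raise ValueError("|ar_coef| must be < 1")
    if covariate_norms is None:
        covariate_norms = {"age": (37.9, 9.4), "expertise": (16.41, 7.69)}

    emap = effect_map
    if not expertise_coupling:
        emap = EffectMap(entries=effect_map.entries[
            effect_map.entries["target"] != "expertise"].reset_index(drop=True))

    roi_ids = parcellation.table["roi_id"].to_numpy()
    networks = parcellation.table["network"].to_numpy()
    r_gt = ground_truth_matrix(covariates, emap, condition, roi_ids, networks,
                               base_within, base_between, covariate_norms)
    chol = np.linalg.cholesky(r_gt + 1e-9 * np.eye(len(r_gt)))

    cond_tag = {"FA": 1, "OM": 2}.get(condition, 9)
    subj_tag = zlib.crc32(str(covariates["subject_id"]).encode()) % (2 ** 31)
    blocks = []
    p = len(roi_ids)
    for b in range(1, n_blocks + 1):
        rng = np.random.default_rng([int(seed), subj_tag, cond_tag, b])
        # neural signal: N(0, R) smoothed by a variance-preserving AR(1)
        innov = rng.standard_normal((n_volumes, p)) @ chol.T
        data = np.empty_like(innov)
        data[0] = innov[0]
        g = np.sqrt(1.0 - ar_coef ** 2)
        for t in range(1, n_volumes):
            data[t] = ar_coef * data[t - 1] + g * innov[t]

        wm = _smooth_walk(rng, n_volumes)
        csf = _smooth_walk(rng, n_volumes)
        motion = np.empty((n_volumes, 6))
        for c in range(3):
            motion[:, c] = 0.05 * _smooth_walk(rng, n_volumes)      # mm
        for c in range(3, 6):
            motion[:, c] = 0.001 * _smooth_walk(rng, n_volumes)     # rad

        # high-motion spikes: sustained translation steps, each producing
        # exactly one volume with FD > 0.5 mm; placed past the discard window
        if n_spikes > 0:
            lo = 6
            candidates = np.arange(lo, n_volumes - 1)
            if len(candidates) < n_spikes:
                raise ValueError("block too short to place the requested spikes")
            while True:
                spikes = np.sort(rng.choice(candidates, size=n_spikes,
                                            replace=False))
                if n_spikes == 1 or np.diff(spikes).min() >= 2:
                    break
            for t in spikes:
                motion[t:, 0] += 0.7 * rng.choice([-1.0, 1.0])
                data[t] += 4.0 * rng.standard_normal(p)

        # contamination: each ROI loads linearly on WM, CSF and the six
        # (standardized) motion traces
        mstd = motion - motion.mean(axis=0)
        sd = mstd.std(axis=0)
        sd[sd == 0] = 1.0
        mstd = mstd / sd
        regressors = np.column_stack([wm, csf, mstd])
        loadings = rng.standard_normal((regressors.shape[1], p))
        data = data + nuisance_gain * regressors @ loadings

        blocks.append(TimeSeriesBlock(
            data=data, tr=tr, subject_id=str(covariates["subject_id"]),
            condition=condition, block_index=b, roi_ids=roi_ids,
            nuisance=np.column_stack([wm, csf]), motion=motion))

    return SimulatedSession(subject_id=str(covariates["subject_id"]),
                            condition=condition, blocks=blocks,
                            ground_truth_r=r_gt, roi_ids=roi_ids)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-level configuration for the synthetic cohort.

    Defaults reproduce the reference study design: 12 meditators, ~88
    volumes per 6-minute block at TR 4.087 s, 3 blocks in each of two
    conditions, a 90-ROI / 14-network parcellation with 7 ROIs lacking
    full grey-matter coverage, and age/expertise marginals calibrated to
    the cohort statistics (age 37.9 +/- 9.4, expertise 16.41 +/- 7.69,
    r = 0.68).
    """

    seed: int
    n_subjects: int = 12
    group: str = "meditator"
    age_mean: float = 37.9
    age_sd: float = 9.4
    exp_mean: float = 16.41
    exp_sd: float = 7.69
    rho: float = 0.68
    conditions: tuple[str, ...] = ("FA", "OM")
    n_blocks: int = 3
    n_volumes: int = 88
    tr: float = 4.087
    n_uncovered_rois: int = 7
    n_age_edges: int = 70
    n_exp_edges_per_condition: int = 50
    n_shared_exp_edges: int = 5
    slope_scale: float = 0.4
    base_within: float = 0.35
    base_between: float = 0.08
    ar_coef: float = 0.3
    nuisance_gain: float = 0.7
    n_spikes: int = 3
    expertise_coupling: bool = True

    @classmethod
    def meditators(cls, seed: int, **kw) -> "CohortConfig":
        return cls(seed=seed, **kw)

    @classmethod
    def novices(cls, seed: int, **kw) -> "CohortConfig":
        """Control-group preset: 10 novices (age 33.0 +/- 4.0), expertise 0,
        expertise coupling disabled."""
        kw.setdefault("n_subjects", 10)
        kw.setdefault("age_mean", 33.0)
        kw.setdefault("age_sd", 4.0)
        kw.setdefault("expertise_coupling", False)
        return cls(seed=seed, group="novice", **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["conditions"] = tuple(d.get("conditions", ("FA", "OM")))
        return cls(**d)


@dataclass
class Cohort:
    """Full synthetic dataset: covariates, parcellation, planted effect map
    and all simulated sessions, keyed by (subject_id, condition)."""

    config: CohortConfig
    covariates: pd.DataFrame
    parcellation: Parcellation
    effect_map: EffectMap
    sessions: dict[tuple[str, str], SimulatedSession] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.covariates["subject_id"])

    def blocks(self, condition: str) -> list[TimeSeriesBlock]:
        out = []
        for sid in self.subject_ids:
            out.extend(self.sessions[(sid, condition)].blocks)
        return out


def generate_cohort(
    config: CohortConfig,
    parcellation: Parcellation | None = None,
    effect_map: EffectMap | None = None,
) -> Cohort:
    """Generate a complete cohort from a configuration.

    A parcellation and effect map may be passed in (e.g. to give a control
    group the meditators' atlas but an independently drawn age effect map);
    otherwise both are drawn from the config seed.
    """
    cov = sample_covariates(config.n_subjects, config.age_mean, config.age_sd,
                            config.exp_mean, config.exp_sd, config.rho,
                            seed=config.seed, group=config.group)
    if parcellation is None:
        parcellation = default_parcellation(list(cov["subject_id"]),
                                            n_uncovered=config.n_uncovered_rois,
                                            seed=config.seed)
    if effect_map is None:
        effect_map = build_effect_map(
            parcellation,
            n_age_edges=config.n_age_edges,
            n_exp_edges_per_condition=config.n_exp_edges_per_condition,
            n_shared_exp_edges=config.n_shared_exp_edges,
            slope_scale=config.slope_scale,
            seed=config.seed,
        )
    norms = {"age": (config.age_mean, config.age_sd),
             "expertise": (config.exp_mean, config.exp_sd)}
    cohort = Cohort(config=config, covariates=cov, parcellation=parcellation,
                    effect_map=effect_map)
    for _, row in cov.iterrows():
        for condition in config.conditions:
            cohort.sessions[(str(row["subject_id"]), condition)] = simulate_session(
                row, effect_map, parcellation, condition,
                n_volumes=config.n_volumes, tr=config.tr,
                base_within=config.base_within, base_between=config.base_between,
                ar_coef=config.ar_coef, nuisance_gain=config.nuisance_gain,
                n_spikes=config.n_spikes, n_blocks=config.n_blocks,
                seed=config.seed, covariate_norms=norms,
                expertise_coupling=config.expertise_coupling)
    return cohort
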