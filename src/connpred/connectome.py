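"""Connectivity matrices and edge-feature tables.

Cleaned blocks become Pearson correlation matrices, Fisher z-transformed,
and vectorized over the upper triangle in a canonical (row-major) edge
order shared by every downstream stage.  A :class:`SampleTable` collects
one feature row per (subject, block) for a single condition together with
the subject covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from connpred.preprocess import preprocess_block
from connpred.simulate import Cohort, TimeSeriesBlock

__all__ = [
    "ConnectivityMatrix",
    "EdgeIndexMap",
    "SampleTable",
    "assemble_samples",
    "correlation_matrix",
    "fisher_z",
    "vectorize_upper",
]


@dataclass
class ConnectivityMatrix:
    """Square ROI-by-ROI connectivity matrix on the r (correlation) or
    z (Fisher-transformed) scale."""

    values: np.ndarray
    scale: str  # "r" or "z"
    roi_ids: np.ndarray
    subject_id: str = ""
    condition: str = ""
    block_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("r", "z"):
            raise ValueError("scale must be 'r' or 'z'")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between feature positions and unordered ROI pairs.

    Edges are the upper triangle (i < j in retained-ROI order) emitted
    row-major; ``pairs[k]`` is the ROI-id pair of feature k.
    """

    roi_ids: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        p = len(self.roi_ids)
        iu = np.triu_indices(p, k=1)
        object.__setattr__(self, "pairs", tuple(
            (self.roi_ids[i], self.roi_ids[j]) for i, j in zip(*iu)))

    @property
    def n_edges(self) -> int:
        return len(self.pairs)

    def index_of(self, roi_a: int, roi_b: int) -> int:
        key = (roi_a, roi_b) if (roi_a, roi_b) in self._lookup() \
            else (roi_b, roi_a)
        return self._lookup()[key]

    def _lookup(self) -> dict[tuple[int, int], int]:
        if not hasattr(self, "_cache"):
            object.__setattr__(self, "_cache",
                               {pr: k for k, pr in enumerate(self.pairs)})
        return self._cache  # type: ignore[attr-defined]

    def to_matrix(self, vector: np.ndarray, diag: float = 0.0) -> np.ndarray:
        """Inverse of vectorization: scatter an edge vector back into a
        symmetric matrix with constant diagonal."""
        p = len(self.roi_ids)
        m = np.full((p, p), diag, dtype=float)
        iu = np.triu_indices(p, k=1)
        m[iu] = vector
        m[(iu[1], iu[0])] = vector
        return m


def correlation_matrix(block: TimeSeriesBlock) -> ConnectivityMatrix:
    """Pairwise Pearson correlation between all ROI series of a block."""
    if block.n_volumes < 3:
        raise ValueError("need at least 3 surviving volumes")
    sd = block.data.std(axis=0)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = ", ".join(str(block.roi_ids[i]) for i in dead)
        raise ValueError(f"zero-variance ROI column(s): {names}")
    r = np.corrcoef(block.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, scale="r", roi_ids=block.roi_ids,
                              subject_id=block.subject_id,
                              condition=block.condition,
                              block_index=block.block_index)


def fisher_z(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Elementwise Fisher z-transformation, z = arctanh(r).

    Variance-stabilizes correlations; monotone and sign-preserving.  The
    diagonal (r = 1, z undefined) is set to 0 and excluded from features.
    """
    if matrix.scale != "r":
        raise ValueError("input must be on the r scale")
    r = matrix.values.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        raise ValueError("off-diagonal |r| = 1: degenerate ROI pair")
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    return ConnectivityMatrix(values=z, scale="z", roi_ids=matrix.roi_ids,
                              subject_id=matrix.subject_id,
                              condition=matrix.condition,
                              block_index=matrix.block_index)


def vectorize_upper(matrix: ConnectivityMatrix,
                    atol: float = 1e-8) -> tuple[np.ndarray, EdgeIndexMap]:
    """Upper-triangle edge vector (length P(P-1)/2) plus its index map."""
    v = matrix.values
    if not np.allclose(v, v.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(v.shape[0], k=1)
    emap = EdgeIndexMap(roi_ids=tuple(int(r) for r in matrix.roi_ids))
    return v[iu].copy(), emap


@dataclass
class SampleTable:
    """Edge-feature rows for one condition.

    features : (n_samples, n_edges) Fisher-z connectivity values
    meta : per-row subject_id, condition, block, age, expertise
    edges : canonical edge index map shared across the pipeline
    """

    features: np.ndarray
    meta: pd.DataFrame
    edges: EdgeIndexMap

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != len(self.meta):
            raise ValueError("features and meta row counts differ")
        if self.features.shape[1] != self.edges.n_edges:
            raise ValueError("feature count does not match edge map")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.features.shape[1]

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.meta["subject_id"]))

    def target(self, name: str) -> np.ndarray:
        return self.meta[name].to_numpy(dtype=float)

    def rows_for(self, subjects) -> np.ndarray:
        return self.meta.index[self.meta["subject_id"].isin(list(subjects))
                               ].to_numpy()

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"e{i}_{j}" for i, j in self.edges.pairs]
        return pd.concat([self.meta,
                          pd.DataFrame(self.features, columns=cols)], axis=1)


def assemble_samples(cohort: Cohort, condition: str,
                     retained_rois: list[int] | None = None,
                     preprocess: bool = True,
                     **preprocess_kwargs) -> SampleTable:
    """Build the per-condition sample table from a cohort.

    Each block is (optionally) cleaned, restricted to the retained ROIs,
    correlated, Fisher z-transformed and vectorized; covariates are joined
    per subject.  With 12 subjects and 3 blocks this yields 36 rows.
    """
    from connpred.preprocess import retain_rois as _retain

    if retained_rois is None:
        retained_rois = _retain(cohort.parcellation)
    cov = cohort.covariates.set_index("subject_id")

    rows, metas, emap = [], [], None
    for sid in cohort.subject_ids:
        session = cohort.sessions.get((sid, condition))
        if session is None:
            raise ValueError(f"missing session: subject {sid}, "
                             f"condition {condition}")
        seen = {b.block_index for b in session.blocks}
        expected = set(range(1, cohort.config.n_blocks + 1))
        if seen != expected:
            raise ValueError(f"subject {sid} {condition}: missing blocks "
                             f"{sorted(expected - seen)}")
        for block in session.blocks:
            b = block
            if preprocess:
                b, _ = preprocess_block(b, **preprocess_kwargs)
            keep = np.isin(b.roi_ids, retained_rois)
            b = b.replace(data=b.data[:, keep], roi_ids=b.roi_ids[keep])
            vec, m = vectorize_upper(fisher_z(correlation_matrix(b)))
            if emap is None:
                emap = m
            elif m != emap:
                raise ValueError("inconsistent edge maps across blocks")
            rows.append(vec)
            metas.append({"subject_id": sid, "condition": condition,
                          "block": block.block_index,
                          "age": float(cov.loc[sid, "age"]),
                          "expertise": float(cov.loc[sid, "expertise"])})
    return SampleTable(features=np.vstack(rows), meta=pd.DataFrame(metas),
                       edges=emap)
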