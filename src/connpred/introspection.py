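"""Model introspection: which edges drive the predictions.

Selection-frequency tables and their cross-task/cross-condition
correlations, consensus weight maps over edges selected in at least a
threshold fraction of folds (default 95%), network- and node-level weight
aggregation, shared-edge maps between conditions, and edgewise group
contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from connpred.connectome import EdgeIndexMap, SampleTable
from connpred.regression import ConnectomeRegressionResults
from connpred.simulate import Parcellation

__all__ = [
    "ConsensusWeights",
    "consensus_weights",
    "frequency_correlation",
    "group_contrast",
    "network_aggregate",
    "node_importance",
    "plot_frequency_scatter",
    "plot_network_matrix",
    "selection_frequency",
    "shared_edges",
]


def selection_frequency(results: ConnectomeRegressionResults) -> pd.Series:
    """Per-edge count of folds in which the edge was selected.

    The maximum possible value is the number of folds actually run; the
    counts over all edges sum to k times that number.
    """
    counts = np.zeros(results.samples.n_edges, dtype=int)
    for f in results.folds:
        counts[f.selected] += 1
    return pd.Series(counts, name="selection_frequency")


def frequency_correlation(freq_a: pd.Series | np.ndarray,
                          freq_b: pd.Series | np.ndarray
                          ) -> tuple[float, float]:
    """Pearson correlation (r, p) between two selection-frequency vectors,
    computed over all edges including never-selected ones."""
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frequency vectors must share the edge index map")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance frequency vector; correlation undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


@dataclass
class ConsensusWeights:
    """Mean z-scored SVR weight per edge, restricted to consensus edges.

    weight : per-edge mean of within-fold z-scored weights over the folds
        where the edge was selected; NaN for non-members
    member : True where the edge was selected in >= threshold of folds
    frequency : raw selection counts
    """

    weight: np.ndarray
    member: np.ndarray
    frequency: np.ndarray
    threshold: float
    n_folds: int
    edges: EdgeIndexMap

    @property
    def member_indices(self) -> np.ndarray:
        return np.where(self.member)[0]

    def to_frame(self, parcellation: Parcellation | None = None
                 ) -> pd.DataFrame:
        """Edge-level table of consensus members (ROI pair, networks,
        weight, frequency)."""
        idx = self.member_indices
        out = pd.DataFrame({
            "edge": idx,
            "roi_i": [self.edges.pairs[k][0] for k in idx],
            "roi_j": [self.edges.pairs[k][1] for k in idx],
            "weight": self.weight[idx],
            "frequency": self.frequency[idx],
        })
        if parcellation is not None:
            net = parcellation.network_of()
            name = parcellation.table.set_index("roi_id")["roi_name"]
            out["roi_i_name"] = out["roi_i"].map(name)
            out["roi_j_name"] = out["roi_j"].map(name)
            out["network_i"] = out["roi_i"].map(net)
            out["network_j"] = out["roi_j"].map(net)
        return out


def consensus_weights(results: ConnectomeRegressionResults,
                      threshold: float = 0.95) -> ConsensusWeights:
    """Average z-scored weights over folds, keeping edges selected in at
    least ``threshold`` of folds.

    Each fold's weight vector (over its k selected edges) is z-scored
    within the fold before averaging, so folds contribute on a common
    scale.
    """
    n_edges = results.samples.n_edges
    n_folds = results.n_folds
    total = np.zeros(n_edges)
    counts = np.zeros(n_edges, dtype=int)
    for f in results.folds:
        w = f.weights
        sd = w.std()
        wz = (w - w.mean()) / sd if sd > 0 else np.zeros_like(w)
        total[f.selected] += wz
        counts[f.selected] += 1
    member = counts >= threshold * n_folds
    if not member.any():
        warnings.warn(f"no edge selected in >= {threshold:.0%} of folds",
                      RuntimeWarning, stacklevel=2)
    weight = np.full(n_edges, np.nan)
    sel = counts > 0
    weight[sel] = total[sel] / counts[sel]
    weight[~member] = np.nan
    return ConsensusWeights(weight=weight, member=member, frequency=counts,
                            threshold=threshold, n_folds=n_folds,
                            edges=results.samples.edges)


def network_aggregate(cw: ConsensusWeights,
                      parcellation: Parcellation) -> pd.DataFrame:
    """Network-by-network matrix of averaged consensus weights, z-scored.

    Cell (A, B) is the mean consensus weight over member edges linking
    networks A and B (within-network on the diagonal); cells are z-scored
    over the non-empty cells and empty cells are NaN.
    """
    nets = parcellation.networks
    net_of = parcellation.network_of()
    sums = pd.DataFrame(0.0, index=nets, columns=nets)
    counts = pd.DataFrame(0, index=nets, columns=nets)
    for k in cw.member_indices:
        i, j = cw.edges.pairs[k]
        a, b = net_of[i], net_of[j]
        for x, y in {(a, b), (b, a)}:
            sums.loc[x, y] += cw.weight[k]
            counts.loc[x, y] += 1
    mean = sums.where(counts > 0) / counts.where(counts > 0)
    # z-score over unique non-empty cells (upper triangle incl. diagonal)
    vals = []
    for ii, a in enumerate(nets):
        for b in nets[ii:]:
            v = mean.loc[a, b]
            if np.isfinite(v):
                vals.append(v)
    vals = np.asarray(vals)
    if vals.size and vals.std() > 0:
        z = (mean - vals.mean()) / vals.std()
    else:
        z = mean - (vals.mean() if vals.size else 0.0)
    return z


def node_importance(cw: ConsensusWeights,
                    parcellation: Parcellation) -> pd.DataFrame:
    """Per-ROI importance: mean |consensus weight| over incident member
    edges.

    Returns a table with the raw incidence average (``importance_raw``), a
    standardized version (mean 0, SD 1 over ROIs with incident edges,
    ``importance_z``), the incident-edge count, and a ``no_edges`` flag for
    ROIs untouched by any consensus edge (importance 0).
    """
    rois = list(parcellation.table["roi_id"])
    total = {r: 0.0 for r in rois}
    count = {r: 0 for r in rois}
    for k in cw.member_indices:
        i, j = cw.edges.pairs[k]
        for r in (i, j):
            if r in total:
                total[r] += abs(cw.weight[k])
                count[r] += 1
    raw = np.array([total[r] / count[r] if count[r] else 0.0 for r in rois])
    touched = np.array([count[r] > 0 for r in rois])
    z = np.zeros_like(raw)
    if touched.any() and raw[touched].std() > 0:
        z[touched] = (raw[touched] - raw[touched].mean()) / raw[touched].std()
    return pd.DataFrame({
        "roi_id": rois,
        "roi_name": parcellation.table["roi_name"].to_numpy(),
        "network": parcellation.table["network"].to_numpy(),
        "importance_raw": raw,
        "importance_z": z,
        "n_edges": [count[r] for r in rois],
        "no_edges": ~touched,
    })


def shared_edges(cw_a: ConsensusWeights,
                 cw_b: ConsensusWeights) -> pd.DataFrame:
    """Edges in both consensus sets, with the mean of the two weights."""
    if cw_a.edges != cw_b.edges:
        raise ValueError("consensus maps use different edge index maps")
    both = np.where(cw_a.member & cw_b.member)[0]
    return pd.DataFrame({
        "edge": both,
        "roi_i": [cw_a.edges.pairs[k][0] for k in both],
        "roi_j": [cw_a.edges.pairs[k][1] for k in both],
        "weight": (cw_a.weight[both] + cw_b.weight[both]) / 2.0,
    })


def group_contrast(samples_a: SampleTable,
                   samples_b: SampleTable) -> pd.DataFrame:
    """Edgewise Welch t-test between two cohorts' connectivities.

    Blocks are averaged to one value per subject per edge first (avoiding
    pseudo-replication), then a two-sided unequal-variance t-test compares
    the groups.  Edges with zero variance in both groups get NaN statistics
    and an ``undefined`` flag.
    """
    if samples_a.edges != samples_b.edges:
        raise ValueError("sample tables use different edge index maps")

    def subject_means(s: SampleTable) -> np.ndarray:
        df = pd.DataFrame(s.features)
        df["subject_id"] = s.meta["subject_id"].to_numpy()
        return df.groupby("subject_id", sort=True).mean().to_numpy()

    a = subject_means(samples_a)
    b = subject_means(samples_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    undefined = ~np.isfinite(t)
    return pd.DataFrame({
        "edge": np.arange(samples_a.n_edges),
        "roi_i": [pr[0] for pr in samples_a.edges.pairs],
        "roi_j": [pr[1] for pr in samples_a.edges.pairs],
        "t": t, "p": p, "undefined": undefined,
    })


# ---------------------------------------------------------------------------
# Plots (optional artifacts)
# ---------------------------------------------------------------------------

def plot_frequency_scatter(freq_a, freq_b, label_a: str = "A",
                           label_b: str = "B", ax=None):
    """Scatter of two selection-frequency vectors with their correlation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    a = np.asarray(freq_a, float)
    b = np.asarray(freq_b, float)
    ax.scatter(a, b, s=8, alpha=0.4, edgecolors="none")
    r, _ = frequency_correlation(a, b)
    lim = max(a.max(), b.max(), 1)
    ax.plot([0, lim], [0, lim], ls="--", c="grey", lw=0.8)
    ax.set_xlabel(f"selection frequency ({label_a})")
    ax.set_ylabel(f"selection frequency ({label_b})")
    ax.set_title(f"r = {r:.2f}")
    return ax


def plot_network_matrix(matrix: pd.DataFrame, ax=None, cmap: str = "RdBu_r"):
    """Heatmap of the network-aggregated weight matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    vals = matrix.to_numpy(dtype=float)
    vmax = np.nanmax(np.abs(vals)) if np.isfinite(vals).any() else 1.0
    im = ax.imshow(vals, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(matrix.columns)),
                  labels=matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), labels=matrix.index, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="z-scored mean weight")
    return ax
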