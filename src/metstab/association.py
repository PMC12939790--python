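"""Index correlations and two-way heatmap clustering.

Pearson correlation among mean yield and the stability indices shows which
indices select for yield and which for pure consistency; significance uses
the usual t transform t = r·sqrt((m−2)/(1−r²)) on m−2 df, two-sided, with a
Holm-adjusted column emitted alongside the raw p-values.

Hierarchical clustering of the yield matrix (rows = genotypes, columns =
environments) groups environments with similar genotype-ranking behaviour
and genotypes with similar response profiles; the heatmap layout permutes
the matrix to the dendrogram leaf order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .met_io import METMatrix

__all__ = [
    "Axis",
    "CorrelationMatrix",
    "ClusterResult",
    "pearson_matrix",
    "hierarchical_cluster",
    "heatmap_layout",
    "dendrogram_to_nested",
]


class Axis(str, enum.Enum):
    GENOTYPES = "genotypes"
    ENVIRONMENTS = "environments"


@dataclass(frozen=True)
class CorrelationMatrix:
    labels: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    p_holm: pd.DataFrame
    n_used: pd.DataFrame


@dataclass(frozen=True)
class ClusterResult:
    axis: Axis
    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    order: tuple[int, ...]  # leaf order (optimal leaf ordering)
    flat_clusters: dict[str, int]
    linkage: str
    distance: str


def pearson_matrix(columns: pd.DataFrame | dict[str, np.ndarray]) -> CorrelationMatrix:
    """Pairwise Pearson correlations over named per-genotype vectors.

    Pairwise-complete: each pair uses the genotypes finite in both columns.
    A zero-variance column gives NaN correlations for its pairs.  Holm
    step-down adjustment is applied over the upper-triangle p-values.
    """
    df = pd.DataFrame(columns)
    labels = tuple(df.columns.astype(str))
    k = len(labels)
    if len(df) < 3:
        raise ValueError("need >= 3 observations")
    r = np.eye(k)
    p = np.zeros((k, k))
    n_used = np.full((k, k), len(df))
    for a in range(k):
        for b in range(a + 1, k):
            x = df.iloc[:, a].to_numpy(dtype=float)
            y = df.iloc[:, b].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            m = int(ok.sum())
            n_used[a, b] = n_used[b, a] = m
            if m < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r[a, b] = r[b, a] = np.nan
                p[a, b] = p[b, a] = np.nan
                continue
            res = stats.pearsonr(x[ok], y[ok])
            r[a, b] = r[b, a] = res.statistic
            p[a, b] = p[b, a] = res.pvalue
    # Holm over the unique off-diagonal tests
    iu = np.triu_indices(k, 1)
    raw = p[iu]
    holm = np.full_like(raw, np.nan)
    finite = np.isfinite(raw)
    if finite.any():
        m_tests = int(finite.sum())
        order = np.argsort(raw[finite])
        adj = np.empty(m_tests)
        running = 0.0
        for rank_pos, idx in enumerate(order):
            val = (m_tests - rank_pos) * raw[finite][idx]
            running = max(running, val)
            adj[idx] = min(1.0, running)
        holm[finite] = adj
    p_holm = np.eye(k) * 0.0
    p_holm[iu] = holm
    p_holm = p_holm + p_holm.T
    np.fill_diagonal(p_holm, 0.0)
    idx = list(labels)
    return CorrelationMatrix(
        labels=labels,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        p_holm=pd.DataFrame(p_holm, index=idx, columns=idx),
        n_used=pd.DataFrame(n_used, index=idx, columns=idx),
    )


def hierarchical_cluster(
    matrix: METMatrix,
    axis: Axis | str = Axis.ENVIRONMENTS,
    linkage: str = "ward",
    distance: str = "euclidean",
    n_clusters: int | None = None,
) -> ClusterResult:
    """Agglomerative clustering of the yield matrix along one axis.

    Default Euclidean/Ward; flat clusters are cut at ``n_clusters`` when
    requested.  Leaf order uses optimal leaf ordering, so the result is
    deterministic and invariant to input row order.
    """
    axis = Axis(axis)
    data = matrix.values if axis is Axis.GENOTYPES else matrix.values.T
    labels = matrix.genotype_ids if axis is Axis.GENOTYPES else matrix.environment_ids
    if len(labels) < 2:
        raise ValueError("need >= 2 items to cluster")
    if linkage not in ("single", "complete", "average", "weighted", "centroid", "median", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    try:
        dists = pdist(data, metric=distance)
    except ValueError as exc:
        raise ValueError(f"unknown distance {distance!r}: {exc}") from None
    z = hierarchy.linkage(dists, method=linkage)
    z = hierarchy.optimal_leaf_ordering(z, dists)
    order = tuple(int(i) for i in hierarchy.leaves_list(z))
    flat: dict[str, int] = {}
    if n_clusters is not None:
        assignments = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
        flat = {labels[i]: int(c) for i, c in enumerate(assignments)}
    return ClusterResult(
        axis=axis,
        labels=tuple(labels),
        linkage_matrix=z,
        order=order,
        flat_clusters=flat,
        linkage=linkage,
        distance=distance,
    )


def heatmap_layout(
    matrix: METMatrix,
    row_cluster: ClusterResult,
    col_cluster: ClusterResult,
    standardize_rows: bool = False,
) -> dict:
    """Matrix permuted to dendrogram leaf order plus dendrogram geometry.

    Values stay raw t/ha unless ``standardize_rows`` z-scores each genotype.
    """
    if row_cluster.axis is not Axis.GENOTYPES or col_cluster.axis is not Axis.ENVIRONMENTS:
        raise ValueError("row_cluster must be over genotypes, col_cluster over environments")
    values = matrix.values
    if standardize_rows:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        values = (values - mu) / np.where(sd == 0, 1.0, sd)
    ri = list(row_cluster.order)
    ci = list(col_cluster.order)
    ordered = values[np.ix_(ri, ci)]
    row_dendro = hierarchy.dendrogram(row_cluster.linkage_matrix, no_plot=True)
    col_dendro = hierarchy.dendrogram(col_cluster.linkage_matrix, no_plot=True)
    return {
        "values": ordered,
        "row_labels": [matrix.genotype_ids[i] for i in ri],
        "col_labels": [matrix.environment_ids[j] for j in ci],
        "row_dendrogram": {"icoord": row_dendro["icoord"], "dcoord": row_dendro["dcoord"]},
        "col_dendrogram": {"icoord": col_dendro["icoord"], "dcoord": col_dendro["dcoord"]},
        "standardized": standardize_rows,
    }


def dendrogram_to_nested(result: ClusterResult) -> dict:
    """Nested (newick-like) serialization of the merge tree for JSON output."""
    n = len(result.labels)
    nodes: dict[int, dict] = {i: {"label": result.labels[i]} for i in range(n)}
    for merge_idx, (a, b, height, _count) in enumerate(result.linkage_matrix):
        nodes[n + merge_idx] = {
            "height": float(height),
            "children": [nodes[int(a)], nodes[int(b)]],
        }
    return nodes[n + len(result.linkage_matrix) - 1]
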