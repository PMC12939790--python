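"""GGE: genotype plus genotype-by-environment decomposition.

Environment-centering the cell-mean matrix, C_ij = X_ij − X̄_j, removes the
environment main effect but keeps the genotype main effect together with
the interaction — the part of variation relevant to cultivar evaluation.
The SVD of C yields the GGE biplot; the same symmetric sqrt(λ) scaling and
sign convention as the AMMI module are used.

The which-won-where view partitions the PC1–PC2 plane: the convex hull of
the genotype markers is drawn, and the perpendicular from the origin to
each hull edge delimits a sector.  Every environment falls in exactly one
sector, and the hull vertex inside a sector is the predicted winner for the
environments there; sectors sharing a winner define mega-environments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .met_io import METMatrix
from .ammi import svd_sign_convention

__all__ = [
    "GGEDecomposition",
    "SectorPartition",
    "DegenerateHullError",
    "gge_decompose",
    "which_won_where",
    "environment_proximity",
]


class DegenerateHullError(ValueError):
    """Genotype markers are collinear; no 2-D hull exists."""


@dataclass(frozen=True)
class GGEDecomposition:
    singular_values: np.ndarray
    genotype_scores: np.ndarray  # g×K, sqrt(λ)-scaled ξ
    environment_scores: np.ndarray  # n×K, sqrt(λ)-scaled η
    explained: np.ndarray
    residual: np.ndarray
    genotype_ids: tuple[str, ...]
    environment_ids: tuple[str, ...]

    @property
    def k_stored(self) -> int:
        return self.genotype_scores.shape[1]


@dataclass(frozen=True)
class SectorPartition:
    hull_genotypes: tuple[str, ...]  # counter-clockwise vertex order
    sector_count: int
    ray_angles: np.ndarray  # radians, sorted ascending, one per sector boundary
    environment_sector: dict[str, int]
    sector_winner: dict[int, str]
    sector_has_environment: dict[int, bool]


def gge_decompose(matrix: METMatrix, scale_by_env_sd: bool = False) -> GGEDecomposition:
    """SVD of the environment-centered (optionally SD-scaled) matrix.

    Default preprocessing is centering only — the common "centering = 2,
    scaling = 0" GGE convention.
    """
    c = matrix.values - matrix.environment_means[None, :]
    if scale_by_env_sd:
        sd = matrix.values.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot scale: an environment has zero variance")
        c = c / sd[None, :]
    g, n = c.shape
    rank = min(g - 1, n)
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    u, v = svd_sign_convention(u[:, :rank], vt.T[:, :rank])
    s = s[:rank]
    ss = s**2
    total = ss.sum()
    explained = ss / total if total > 0 else np.zeros_like(ss)
    sqrt_s = np.sqrt(s)
    gen = u * sqrt_s
    env = v * sqrt_s
    return GGEDecomposition(
        singular_values=s,
        genotype_scores=gen,
        environment_scores=env,
        explained=explained,
        residual=c - gen @ env.T,
        genotype_ids=matrix.genotype_ids,
        environment_ids=matrix.environment_ids,
    )


def _wrap(a: float) -> float:
    """Angle into [0, 2π)."""
    return a % (2.0 * math.pi)


def which_won_where(decomp: GGEDecomposition) -> SectorPartition:
    """Sector the PC1–PC2 plane by perpendiculars to the genotype hull.

    Hull vertices are taken counter-clockwise; the boundary ray for edge
    (v_a, v_b) is the direction perpendicular to that edge pointing away
    from the origin, which passes between the two vertices' angular
    positions.  An environment exactly on a ray goes to the
    counter-clockwise sector.  Collinear genotype clouds raise
    :class:`DegenerateHullError`; callers may fall back to a two-sector
    split along the first axis.
    """
    if decomp.k_stored < 2:
        raise ValueError("need >= 2 components")
    pts = decomp.genotype_scores[:, :2]
    if len(pts) < 3:
        raise ValueError("need >= 3 genotypes")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(f"genotype markers are degenerate: {exc}") from None
    verts = list(hull.vertices)  # counter-clockwise for 2-D qhull
    m = len(verts)
    # outward normal of each hull edge verts[a] -> verts[a+1]; for a CCW
    # polygon the outward normal of edge (p, q) is (q_y - p_y rotated):
    # (edge_y, -edge_x)
    normals = []
    for a in range(m):
        p, q = pts[verts[a]], pts[verts[(a + 1) % m]]
        edge = q - p
        normal = np.array([edge[1], -edge[0]])
        normals.append(_wrap(math.atan2(normal[1], normal[0])))
    normals = np.array(normals)

    # the sector won by vertex verts[a] is its normal cone: the angular
    # interval from the normal of its incoming edge (verts[a-1] -> verts[a])
    # to the normal of its outgoing edge (verts[a] -> verts[a+1]); any
    # direction in that cone attains its maximum projection at verts[a]
    order = np.argsort(normals)
    sorted_rays = normals[order]

    def sector_of(angle: float) -> int:
        """Index into the sorted ray list: sector i spans
        [ray_i, ray_{i+1}); an angle exactly on a ray joins the
        counter-clockwise (following) sector."""
        a = _wrap(angle)
        idx = int(np.searchsorted(sorted_rays, a, side="right")) - 1
        return idx % m

    # sector starting at the normal of edge (verts[a] -> verts[a+1]) is the
    # normal cone of verts[a+1]
    winners: dict[int, str] = {}
    for pos, edge_idx in enumerate(order):
        winners[pos] = decomp.genotype_ids[verts[(edge_idx + 1) % m]]
    env_pts = decomp.environment_scores[:, :2]
    env_sector = {
        decomp.environment_ids[j]: sector_of(math.atan2(env_pts[j][1], env_pts[j][0]))
        for j in range(len(env_pts))
    }
    has_env = {s: s in env_sector.values() for s in range(m)}
    return SectorPartition(
        hull_genotypes=tuple(decomp.genotype_ids[v] for v in verts),
        sector_count=m,
        ray_angles=sorted_rays,
        environment_sector=env_sector,
        sector_winner=winners,
        sector_has_environment=has_env,
    )


def environment_proximity(decomp: GGEDecomposition) -> dict[str, pd.DataFrame]:
    """Distances in PC1–PC2 space.

    Returns the genotype-to-environment distance matrix, origin distances
    for genotypes and environments, and the broadly-favorable flag: among
    genotypes with positive PC1, the ones with |PC2| below the genotype
    median are marked (high mean performance, low interaction).
    """
    if decomp.k_stored < 2:
        raise ValueError("need >= 2 components")
    gp = decomp.genotype_scores[:, :2]
    ep = decomp.environment_scores[:, :2]
    dist = np.linalg.norm(gp[:, None, :] - ep[None, :, :], axis=2)
    dist_df = pd.DataFrame(
        dist, index=list(decomp.genotype_ids), columns=list(decomp.environment_ids)
    )
    abs_pc2 = np.abs(gp[:, 1])
    favorable = (gp[:, 0] > 0) & (abs_pc2 <= np.median(abs_pc2))
    gen_df = pd.DataFrame(
        {
            "id": list(decomp.genotype_ids),
            "PC1": gp[:, 0],
            "PC2": gp[:, 1],
            "origin_distance": np.linalg.norm(gp, axis=1),
            "nearest_environment": [
                decomp.environment_ids[int(j)] for j in dist.argmin(axis=1)
            ],
            "broadly_favorable": favorable,
        }
    )
    env_df = pd.DataFrame(
        {
            "id": list(decomp.environment_ids),
            "PC1": ep[:, 0],
            "PC2": ep[:, 1],
            "origin_distance": np.linalg.norm(ep, axis=1),
            "nearest_genotype": [decomp.genotype_ids[int(i)] for i in dist.argmin(axis=0)],
        }
    )
    return {"distances": dist_df, "genotypes": gen_df, "environments": env_df}
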