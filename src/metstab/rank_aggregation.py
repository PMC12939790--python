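"""Harmonic-rank aggregation of stability indices (SID / RSID).

The univariate indices rarely agree on which genotypes are stable, so they
are combined into a single score:

1. rank genotypes within each index so that rank 1 marks the favorable
   end (average ranks for ties);
2. aggregate each genotype's ranks by their harmonic mean — the SID
   (stability identity) score; its ascending rank is the RSID.

Two ranking directions are supported.  The default ``stability`` mode
ranks each index in its stability-favorable direction — ascending for the
dispersion indices (S², CV, W², σ², S²d), descending for R², and distance
from 1 for the joint-regression slope b — which is the direction the
method's published rankings exhibit.  The alternative ``yield_aligned``
mode applies the correlation rule verbatim: each index's Pearson
correlation with mean yield is computed, and indices correlating
negatively have their values inverted (reciprocals) before ascending
ranking.  The two modes disagree exactly when stable genotypes are also
the high-yielding ones, in which case ``yield_aligned`` reverses the
stability direction of every dispersion index; ``stability`` is therefore
the default.  Yield correlations are reported in both modes.

The harmonic mean rewards genotypes that are top-ranked by at least some
indices, unlike the arithmetic mean rank which is also reported.  Finally
genotypes are classified into yield-vs-rank quadrants: group A holds the
desirable corner (above-average yield, better-than-average aggregate rank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .met_io import RunConfig
from .univariate import INDEX_COLUMNS, StabilityRecord, stability_table_frame

__all__ = [
    "Orientation",
    "RankTable",
    "SIDResult",
    "orient_indices",
    "rank_by_index",
    "build_rank_table",
    "sid",
    "quadrant_classify",
    "sid_pipeline",
    "STABILITY_DIRECTIONS",
]


@dataclass(frozen=True)
class Orientation:
    """How one index enters the ranking, with the correlation that decided it."""

    index: str
    inverted: bool
    yield_correlation: float


@dataclass(frozen=True)
class RankTable:
    """Per-index genotype ranks (columns) after orientation."""

    genotypes: tuple[str, ...]
    ranks: pd.DataFrame  # rows genotypes, columns index names
    orientations: tuple[Orientation, ...]


@dataclass(frozen=True)
class SIDResult:
    genotype: str
    sid: float
    rsid: float
    mean_rank: float
    quadrant: str = ""
    boundary: bool = False


def orient_indices(
    table: pd.DataFrame | Sequence[StabilityRecord],
    yields: np.ndarray | None = None,
    index_columns: Sequence[str] = INDEX_COLUMNS,
) -> list[Orientation]:
    """Decide each index's direction from its Pearson correlation with yield.

    Negative correlation marks the index ``inverted`` (reciprocal values
    before ranking); a zero-variance column stays as-is with a warning.
    """
    df = _as_frame(table)
    y = np.asarray(yields if yields is not None else df["mean"], dtype=float)
    if len(df) < 3:
        raise ValueError("orientation needs >= 3 genotypes")
    out: list[Orientation] = []
    for col in index_columns:
        vals = df[col].to_numpy(dtype=float)
        ok = np.isfinite(vals) & np.isfinite(y)
        if ok.sum() < 3 or np.std(vals[ok]) == 0 or np.std(y[ok]) == 0:
            warnings.warn(f"index {col!r} has no usable variance; oriented as-is", stacklevel=2)
            out.append(Orientation(col, inverted=False, yield_correlation=np.nan))
            continue
        r = float(stats.pearsonr(vals[ok], y[ok]).statistic)
        out.append(Orientation(col, inverted=r < 0, yield_correlation=r))
    return out


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return stability_table_frame(list(table))


def rank_by_index(values: np.ndarray, inverted: bool = False) -> np.ndarray:
    """Rank genotypes on one index: smaller oriented value → rank nearer 1.

    Inversion uses reciprocals when every value is positive (as the method
    prescribes); with non-positive values present the reciprocal is not
    order-reversing, so ranks are reversed directly — the same ordering for
    any all-positive column.  Missing values rank last (average-tied).
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    work = values.copy()
    if inverted:
        if np.all(work[finite] > 0):
            work[finite] = 1.0 / work[finite]
        else:
            work[finite] = -work[finite]
    # push missing to the bottom deterministically
    if finite.all():
        return stats.rankdata(work, method="average")
    ranks = np.empty(values.size)
    ranks[finite] = stats.rankdata(work[finite], method="average")
    n_missing = (~finite).sum()
    worst = finite.sum() + (n_missing + 1) / 2.0
    ranks[~finite] = worst
    return ranks


#: Stability-favorable ranking direction per index, used by the default
#: mode: "asc" = smaller is better, "desc" = larger is better,
#: "near_one" = closer to 1 is better (slope b).
STABILITY_DIRECTIONS: dict[str, str] = {
    "S2": "asc",
    "CV": "asc",
    "SD": "asc",
    "W2": "asc",
    "sigma2": "asc",
    "b": "near_one",
    "S2d": "asc",
    "R2": "desc",
}


def build_rank_table(
    table: pd.DataFrame | Sequence[StabilityRecord],
    config: RunConfig | None = None,
    index_columns: Sequence[str] = INDEX_COLUMNS,
    mode: str = "stability",
) -> RankTable:
    """Rank every index column; optionally add a yield rank (rank 1 =
    highest yield) when ``config.sid_include_yield``.

    ``mode="stability"`` (default) ranks each index in its
    stability-favorable direction; ``mode="yield_aligned"`` applies the
    correlation-sign inversion rule instead (see module docstring).
    """
    if mode not in ("stability", "yield_aligned"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or RunConfig()
    df = _as_frame(table)
    orientations = orient_indices(df, index_columns=index_columns)
    ranks = {}
    for o in orientations:
        vals = df[o.index].to_numpy(dtype=float)
        if mode == "yield_aligned":
            ranks[o.index] = rank_by_index(vals, o.inverted)
            continue
        direction = STABILITY_DIRECTIONS.get(o.index, "asc")
        if direction == "near_one":
            ranks[o.index] = rank_by_index(np.abs(vals - 1.0))
        else:
            ranks[o.index] = rank_by_index(vals, inverted=(direction == "desc"))
    if config.sid_include_yield:
        ranks["yield"] = rank_by_index(-df["mean"].to_numpy(dtype=float))
        orientations = [*orientations, Orientation("yield", False, 1.0)]
    rank_df = pd.DataFrame(ranks, index=list(df["genotype"]))
    return RankTable(tuple(df["genotype"]), rank_df, tuple(orientations))


def sid(rank_table: RankTable) -> list[SIDResult]:
    """Aggregate per-index ranks into SID (harmonic mean of ranks) and RSID.

    Missing ranks are excluded from that genotype's harmonic mean; every
    genotype needs at least one finite rank.  Smaller SID is better; RSID
    ranks SID ascending with average ties.
    """
    r = rank_table.ranks.to_numpy(dtype=float)
    if np.nanmin(r) <= 0:
        raise ValueError("ranks must be positive")
    finite = np.isfinite(r)
    if not finite.any(axis=1).all():
        bad = [g for g, ok in zip(rank_table.genotypes, finite.any(axis=1)) if not ok]
        raise ValueError(f"genotypes with no finite rank: {bad}")
    with np.errstate(invalid="ignore"):
        k = finite.sum(axis=1)
        inv_sum = np.where(finite, 1.0 / r, 0.0).sum(axis=1)
        sid_vals = k / inv_sum
        mean_rank = np.where(finite, r, 0.0).sum(axis=1) / k
    rsid = stats.rankdata(sid_vals, method="average")
    return [
        SIDResult(genotype=g, sid=float(s), rsid=float(rr), mean_rank=float(m))
        for g, s, rr, m in zip(rank_table.genotypes, sid_vals, rsid, mean_rank)
    ]


def quadrant_classify(
    results: Sequence[SIDResult],
    yields: Mapping[str, float] | np.ndarray,
    rank_attr: str = "rsid",
) -> list[SIDResult]:
    """Label each genotype by its yield-vs-aggregate-rank quadrant.

    With yield on the vertical axis and rank on the horizontal (rank 1 at
    the left), quadrants run counter-clockwise from the desirable corner:

    * A — yield above the mean, rank better (smaller) than the mean rank;
    * B — yield below the mean, rank better than the mean;
    * C — yield below the mean, rank worse than the mean;
    * D — yield above the mean, rank worse than the mean.

    Genotypes exactly on a mean line go to the favorable side and are
    flagged ``boundary``.
    """
    if isinstance(yields, Mapping):
        y = np.array([float(yields[r.genotype]) for r in results])
    else:
        y = np.asarray(yields, dtype=float)
    ranks = np.array([getattr(r, rank_attr) for r in results], dtype=float)
    y_mean, r_mean = y.mean(), ranks.mean()
    out = []
    for res, yi, ri in zip(results, y, ranks):
        high_yield = yi >= y_mean
        good_rank = ri <= r_mean
        quadrant = {
            (True, True): "A",
            (False, True): "B",
            (False, False): "C",
            (True, False): "D",
        }[(high_yield, good_rank)]
        out.append(
            SIDResult(
                genotype=res.genotype,
                sid=res.sid,
                rsid=res.rsid,
                mean_rank=res.mean_rank,
                quadrant=quadrant,
                boundary=bool(yi == y_mean or ri == r_mean),
            )
        )
    return out


def sid_pipeline(
    table: pd.DataFrame | Sequence[StabilityRecord],
    config: RunConfig | None = None,
    mode: str = "stability",
) -> tuple[RankTable, list[SIDResult], pd.DataFrame]:
    """Ranking → SID/RSID → quadrants, returning the rank table,
    classified results, and a flat output frame."""
    config = config or RunConfig()
    df = _as_frame(table)
    rank_table = build_rank_table(df, config, mode=mode)
    results = sid(rank_table)
    yields = dict(zip(df["genotype"], df["mean"].astype(float)))
    results = quadrant_classify(results, yields)
    flat = rank_table.ranks.add_prefix("rank_").copy()
    flat.insert(0, "genotype", list(rank_table.genotypes))
    flat["SID"] = [r.sid for r in results]
    flat["RSID"] = [r.rsid for r in results]
    flat["mean_rank"] = [r.mean_rank for r in results]
    flat["quadrant"] = [r.quadrant for r in results]
    flat["boundary"] = [r.boundary for r in results]
    flat = flat.reset_index(drop=True)
    return rank_table, results, flat
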