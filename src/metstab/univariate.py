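"""Per-genotype univariate yield-stability indices.

Eight classical statistics computed from the genotype-by-environment
cell-mean matrix, per genotype i over n environments:

* environmental variance  S²_i = Σ_j (X_ij − X̄_i)² / (n−1)
* standard deviation      SD_i = sqrt(S²_i)
* coefficient of variation CV_i = 100·SD_i / X̄_i
* Wricke's ecovalence     W²_i = Σ_j (X_ij − X̄_i − X̄_j + X̄)²
* Shukla's stability variance σ²_i (two estimators, see ``shukla_variance``)
* joint-regression slope  b_i on the environmental index E_j = X̄_j
* deviation from regression S²d_i = Σ_j residual² / (n−2)
* coefficient of determination R²_i of the genotype's regression

Lower S², CV, W², σ² and S²d mean more stable; b near 1 means average
responsiveness; higher R² means a more predictable response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .met_io import METMatrix, RunConfig, ShuklaMode

__all__ = [
    "JointRegressionFit",
    "StabilityRecord",
    "UndefinedStatisticError",
    "environmental_variance",
    "coefficient_of_variation",
    "standard_deviation",
    "wricke_ecovalence",
    "shukla_variance",
    "joint_regression",
    "compute_index_table",
    "stability_table_frame",
    "INDEX_COLUMNS",
]

#: Stability-index columns of the output table (ranking candidates).
INDEX_COLUMNS = ("S2", "CV", "W2", "sigma2", "b", "S2d", "R2")


class UndefinedStatisticError(ValueError):
    """The statistic's divisor vanishes for this input size."""


@dataclass(frozen=True)
class JointRegressionFit:
    """Finlay–Wilkinson / Eberhart–Russell regression of one genotype's
    yields on the environmental index."""

    b: float
    s2d: float
    r2: float
    fitted: np.ndarray


@dataclass(frozen=True)
class StabilityRecord:
    genotype: str
    mean: float
    s2: float
    cv: float
    sd: float
    w2: float
    sigma2_paper: float
    sigma2_classical: float
    fit: JointRegressionFit


def environmental_variance(row: np.ndarray) -> float:
    """Sample variance of a genotype's yields across environments (n−1)."""
    row = np.asarray(row, dtype=float)
    if row.size < 2:
        raise UndefinedStatisticError("environmental variance needs >= 2 environments")
    return float(row.var(ddof=1))


def standard_deviation(row: np.ndarray) -> float:
    return float(np.sqrt(environmental_variance(row)))


def coefficient_of_variation(row: np.ndarray) -> float:
    """CV_i = 100 · SD_i / X̄_i, in percent.  Requires a positive mean."""
    row = np.asarray(row, dtype=float)
    mean = row.mean()
    if mean <= 0:
        raise UndefinedStatisticError(f"CV undefined for non-positive mean {mean}")
    return 100.0 * standard_deviation(row) / mean


def _w2_all(matrix: METMatrix) -> np.ndarray:
    z = matrix.interaction_residuals()
    return (z**2).sum(axis=1)


def wricke_ecovalence(matrix: METMatrix, genotype: str) -> float:
    """W²_i: genotype i's share of the interaction sum of squares.

    Squared norm of genotype i's row of the double-centered matrix; summing
    over genotypes recovers SS_GE exactly.
    """
    i = matrix.genotype_ids.index(_lookup(matrix, genotype))
    return float(_w2_all(matrix)[i])


def _lookup(matrix: METMatrix, genotype: str) -> str:
    gt = str(genotype)
    if gt not in matrix.genotype_ids:
        raise KeyError(f"unknown genotype {genotype!r}")
    return gt


def shukla_variance(matrix: METMatrix, genotype: str, mode: ShuklaMode | str) -> float:
    """Shukla stability variance for one genotype.

    ``paper_literal``: W²_i / (n−1) — the interaction mean square of the
    genotype's row.  ``classical``: Shukla's (1972) unbiased
    variance-component estimator

        σ²_i = [g(g−1)·W²_i − Σ_m W²_m] / [(g−1)(g−2)(n−1)],

    which can be negative by sampling error and needs g ≥ 3.
    """
    mode = ShuklaMode(mode)
    g, n = matrix.values.shape
    i = matrix.genotype_ids.index(_lookup(matrix, genotype))
    w2 = _w2_all(matrix)
    if mode is ShuklaMode.PAPER_LITERAL:
        return float(w2[i] / (n - 1))
    if g < 3:
        raise UndefinedStatisticError("classical Shukla estimator needs >= 3 genotypes")
    return float((g * (g - 1) * w2[i] - w2.sum()) / ((g - 1) * (g - 2) * (n - 1)))


def joint_regression(row: np.ndarray, env_index: np.ndarray) -> JointRegressionFit:
    """Regress one genotype's yields on the environmental index.

    The line is anchored at (Ē, X̄_i), so b_i is the least-squares slope,
    S²d_i the residual mean square on n−2 df, and R²_i the usual coefficient
    of determination.  A flat genotype (zero variance) has an undefined R²,
    reported as NaN with a warning.
    """
    row = np.asarray(row, dtype=float)
    env_index = np.asarray(env_index, dtype=float)
    n = row.size
    if n < 3:
        raise UndefinedStatisticError("joint regression needs >= 3 environments (n-2 divisor)")
    e_dev = env_index - env_index.mean()
    sxx = float(e_dev @ e_dev)
    if sxx == 0.0:
        raise UndefinedStatisticError("environmental index is constant; slope undefined")
    x_dev = row - row.mean()
    b = float(x_dev @ e_dev) / sxx
    fitted = row.mean() + b * e_dev
    resid = row - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(x_dev @ x_dev)
    s2d = ss_res / (n - 2)
    if ss_tot == 0.0:
        warnings.warn("zero-variance genotype: R^2 undefined, reported as NaN", stacklevel=2)
        r2 = np.nan
    else:
        r2 = 1.0 - ss_res / ss_tot
    return JointRegressionFit(b=b, s2d=s2d, r2=r2, fitted=fitted)


def compute_index_table(
    matrix: METMatrix, config: RunConfig | None = None
) -> list[StabilityRecord]:
    """All eight indices for every genotype, in input genotype order.

    Per-genotype failures (e.g. CV with non-positive mean) become NaN
    entries rather than aborting the table.
    """
    config = config or RunConfig()
    env_idx = matrix.environment_means
    w2 = _w2_all(matrix)
    g, n = matrix.values.shape
    out: list[StabilityRecord] = []
    for i, gt in enumerate(matrix.genotype_ids):
        row = matrix.values[i]
        s2 = environmental_variance(row)
        sd = float(np.sqrt(s2))
        try:
            cv = coefficient_of_variation(row)
        except UndefinedStatisticError:
            cv = np.nan
        sig_paper = float(w2[i] / (n - 1))
        if g >= 3:
            sig_classical = float(
                (g * (g - 1) * w2[i] - w2.sum()) / ((g - 1) * (g - 2) * (n - 1))
            )
        else:
            sig_classical = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = joint_regression(row, env_idx)
        out.append(
            StabilityRecord(
                genotype=gt,
                mean=float(row.mean()),
                s2=s2,
                cv=cv,
                sd=sd,
                w2=float(w2[i]),
                sigma2_paper=sig_paper,
                sigma2_classical=sig_classical,
                fit=fit,
            )
        )
    return out


def stability_table_frame(
    records: list[StabilityRecord], config: RunConfig | None = None
) -> pd.DataFrame:
    """Tabular view; ``sigma2`` mirrors the configured Shukla mode so a
    single column feeds ranking while both estimators remain visible."""
    config = config or RunConfig()
    df = pd.DataFrame(
        {
            "genotype": [r.genotype for r in records],
            "mean": [r.mean for r in records],
            "S2": [r.s2 for r in records],
            "CV": [r.cv for r in records],
            "SD": [r.sd for r in records],
            "W2": [r.w2 for r in records],
            "sigma2_paper": [r.sigma2_paper for r in records],
            "sigma2_classical": [r.sigma2_classical for r in records],
            "b": [r.fit.b for r in records],
            "S2d": [r.fit.s2d for r in records],
            "R2": [r.fit.r2 for r in records],
        }
    )
    mode_col = (
        "sigma2_paper" if config.shukla_mode is ShuklaMode.PAPER_LITERAL else "sigma2_classical"
    )
    df["sigma2"] = df[mode_col]
    return df
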