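"""AMMI: additive main effects and multiplicative interaction.

The model for the cell means is

    X_ij = μ + G_i + E_j + Σ_k λ_k γ_ik δ_jk + ρ_ij,

where the multiplicative part is the SVD of the double-centered matrix
Z_ij = X_ij − X̄_i − X̄_j + X̄.  Scores are stored in the symmetric
sqrt(λ) scaling, so the genotype score times the environment score summed
over components reconstructs Z.  Component signs are fixed so the
environment score of largest magnitude on each axis is positive, making
output deterministic across linear-algebra backends.

The combined ANOVA follows the augmented-design layout: environment,
genotype and interaction sums of squares come from the unreplicated line
cell values; the replicated checks supply the replication-within-environment
stratum and the residual error mean square.  F-tests use the
replication-within-environment mean square for the environment effect and
the check residual mean square for everything else.  Interaction principal
components carry Gollob degrees of freedom g + n − 1 − 2k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .met_io import METMatrix, Role, RunConfig, TrialRecord, ValidationError, to_matrix

__all__ = [
    "AMMIDecomposition",
    "AnovaTable",
    "combined_anova",
    "ammi_decompose",
    "ipca_distance",
    "ammi_biplot_coords",
    "svd_sign_convention",
]


@dataclass(frozen=True)
class AMMIDecomposition:
    grand_mean: float
    genotype_effects: np.ndarray  # G_i, sum 0
    environment_effects: np.ndarray  # E_j, sum 0
    singular_values: np.ndarray  # λ_k descending
    genotype_scores: np.ndarray  # g×K, sqrt(λ)-scaled
    environment_scores: np.ndarray  # n×K, sqrt(λ)-scaled
    explained: np.ndarray  # λ_k² / Σ λ², over full rank
    residual: np.ndarray  # Z − k_max-term reconstruction
    genotype_ids: tuple[str, ...]
    environment_ids: tuple[str, ...]

    @property
    def k_stored(self) -> int:
        return self.genotype_scores.shape[1]


@dataclass(frozen=True)
class AnovaTable:
    """Combined-ANOVA rows plus the trial coefficient of variation."""

    table: pd.DataFrame  # source, df, SS, MS, F, p, sig, accumulated_pct
    cv_percent: float
    grand_mean: float

    def row(self, source: str) -> pd.Series:
        match = self.table[self.table["source"] == source]
        if match.empty:
            raise KeyError(f"no ANOVA row {source!r}")
        return match.iloc[0]


def _sig_code(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def svd_sign_convention(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so the environment (column-side) loading of
    largest magnitude is positive; ties broken by the first extreme index."""
    u, v = u.copy(), v.copy()
    for k in range(v.shape[1]):
        jmax = int(np.argmax(np.abs(v[:, k])))
        if v[jmax, k] < 0:
            v[:, k] *= -1
            u[:, k] *= -1
    return u, v


def ammi_decompose(matrix: METMatrix, k_max: int | None = None) -> AMMIDecomposition:
    """Fit the AMMI model to a complete cell-mean matrix.

    ``k_max`` components are retained for the reconstruction/residual
    (default: full rank min(g−1, n−1)); singular values and explained
    proportions are always reported at full rank.
    """
    g, n = matrix.values.shape
    full_rank = min(g - 1, n - 1)
    if k_max is None:
        k_max = full_rank
    if not (0 <= k_max <= full_rank):
        raise ValueError(f"k_max must be in [0, {full_rank}], got {k_max}")
    z = matrix.interaction_residuals()
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    u, v = svd_sign_convention(u[:, :full_rank], vt.T[:, :full_rank])
    s = s[:full_rank]
    ss = s**2
    total = ss.sum()
    explained = ss / total if total > 0 else np.zeros_like(ss)
    sqrt_s = np.sqrt(s)
    gen_scores = u * sqrt_s
    env_scores = v * sqrt_s
    recon = gen_scores[:, :k_max] @ env_scores[:, :k_max].T
    return AMMIDecomposition(
        grand_mean=matrix.grand_mean,
        genotype_effects=matrix.genotype_means - matrix.grand_mean,
        environment_effects=matrix.environment_means - matrix.grand_mean,
        singular_values=s,
        genotype_scores=gen_scores,
        environment_scores=env_scores,
        explained=explained,
        residual=z - recon,
        genotype_ids=matrix.genotype_ids,
        environment_ids=matrix.environment_ids,
    )


def ipca_distance(decomp: AMMIDecomposition, k: int = 2) -> np.ndarray:
    """Per-genotype Euclidean norm of the first ``k`` scaled interaction
    scores; small distances mark AMMI-stable genotypes."""
    if not (1 <= k <= decomp.k_stored):
        raise ValueError(f"k must be in [1, {decomp.k_stored}]")
    return np.linalg.norm(decomp.genotype_scores[:, :k], axis=1)


def ammi_biplot_coords(decomp: AMMIDecomposition) -> dict[str, pd.DataFrame]:
    """Coordinate sets for the two classic AMMI views: mean vs IPCA1 and
    IPCA1 vs IPCA2, for genotypes and environments."""
    if decomp.k_stored < 2:
        raise ValueError("need >= 2 stored components for biplot coordinates")
    gen_mean = decomp.grand_mean + decomp.genotype_effects
    env_mean = decomp.grand_mean + decomp.environment_effects
    gen = pd.DataFrame(
        {
            "id": list(decomp.genotype_ids),
            "mean": gen_mean,
            "IPCA1": decomp.genotype_scores[:, 0],
            "IPCA2": decomp.genotype_scores[:, 1],
        }
    )
    env = pd.DataFrame(
        {
            "id": list(decomp.environment_ids),
            "mean": env_mean,
            "IPCA1": decomp.environment_scores[:, 0],
            "IPCA2": decomp.environment_scores[:, 1],
        }
    )
    return {"genotypes": gen, "environments": env}


# ---------------------------------------------------------------------------
# combined ANOVA for the augmented design


def _check_strata(check_recs: Sequence[TrialRecord]):
    """Replication-within-environment SS and the check residual, with df
    derived from the block labels actually present."""
    df = pd.DataFrame(
        {
            "env": [r.environment for r in check_recs],
            "block": [r.block for r in check_recs],
            "genotype": [r.genotype for r in check_recs],
            "y": [r.yield_ for r in check_recs],
        }
    )
    ss_rep = 0.0
    df_rep = 0
    ss_err = 0.0
    df_err = 0
    for _, sub in df.groupby("env"):
        env_mean = sub["y"].mean()
        blocks = sub.groupby("block")["y"]
        ss_rep += float((blocks.count() * (blocks.mean() - env_mean) ** 2).sum())
        df_rep += blocks.ngroups - 1
        # residual: within-environment variation not explained by block or check
        block_mean = sub.groupby("block")["y"].transform("mean")
        geno_mean = sub.groupby("genotype")["y"].transform("mean")
        resid = sub["y"] - block_mean - geno_mean + env_mean
        ss_err += float((resid**2).sum())
        df_err += len(sub) - blocks.ngroups - sub["genotype"].nunique() + 1
    if df_rep <= 0 or df_err <= 0:
        raise ValidationError(
            "checks are not replicated across blocks within environments; "
            "replication and residual strata are not estimable"
        )
    return ss_rep, df_rep, ss_err, df_err


def combined_anova(
    records: Sequence[TrialRecord],
    config: RunConfig | None = None,
    error_ms: float | None = None,
    error_df: int | None = None,
) -> AnovaTable:
    """Combined analysis of variance for an augmented MET.

    Main and interaction effects come from the unreplicated line cells;
    the replicated checks estimate the replication-within-environment
    stratum and the residual error (or supply ``error_ms``/``error_df``
    externally when no checks exist).  The interaction is further split
    into its principal components (Gollob df), with accumulated percent of
    the interaction sum of squares.
    """
    config = config or RunConfig()
    records = list(records)
    lines = [r for r in records if r.role is Role.LINE]
    checks = [r for r in records if r.role is Role.CHECK]
    if not lines:
        raise ValidationError("no line records for the combined ANOVA")
    matrix = to_matrix(lines, config)
    g, n = matrix.values.shape
    grand = matrix.grand_mean
    ss_env = float(g * ((matrix.environment_means - grand) ** 2).sum())
    ss_gen = float(n * ((matrix.genotype_means - grand) ** 2).sum())
    z = matrix.interaction_residuals()
    ss_ge = float((z**2).sum())
    df_env, df_gen, df_ge = n - 1, g - 1, (g - 1) * (n - 1)

    if checks:
        ss_rep, df_rep, ss_err, df_err = _check_strata(checks)
        ms_err = ss_err / df_err
    elif error_ms is not None and error_df is not None:
        ss_rep = df_rep = None
        ms_err, ss_err, df_err = float(error_ms), float(error_ms) * int(error_df), int(error_df)
    else:
        raise ValidationError(
            "no replicated checks: supply error_ms and error_df for the F-tests"
        )

    decomp = ammi_decompose(matrix)
    pc_ss = decomp.singular_values**2
    rows = []

    def add(source, dfree, ss, denom_ms, denom_df, acc=np.nan):
        ms = ss / dfree if dfree > 0 else np.nan
        if denom_ms is not None and denom_ms > 0 and dfree > 0:
            f = ms / denom_ms
            p = float(stats.f.sf(f, dfree, denom_df))
        else:
            f, p = np.nan, np.nan
        rows.append(
            {
                "source": source,
                "df": dfree,
                "SS": ss,
                "MS": ms,
                "F": f,
                "p": p,
                "sig": _sig_code(p),
                "accumulated_pct": acc,
            }
        )

    if checks:
        ms_rep = ss_rep / df_rep
        add("Environment", df_env, ss_env, ms_rep, df_rep)
        add("Replication(Env)", df_rep, ss_rep, ms_err, df_err)
    else:
        add("Environment", df_env, ss_env, ms_err, df_err)
    add("Genotype", df_gen, ss_gen, ms_err, df_err)
    add("Env x Gen", df_ge, ss_ge, ms_err, df_err)
    acc = 0.0
    for k, ssk in enumerate(pc_ss, start=1):
        acc += 100.0 * ssk / ss_ge if ss_ge > 0 else 0.0
        df_pc = g + n - 1 - 2 * k
        add(f"PC{k}", df_pc, float(ssk), ms_err, df_err, acc=acc)
    rows.append(
        {
            "source": "Sum",
            "df": df_ge,
            "SS": ss_ge,
            "MS": ss_ge / df_ge if df_ge else np.nan,
            "F": np.nan,
            "p": np.nan,
            "sig": "",
            "accumulated_pct": 100.0 if ss_ge > 0 else np.nan,
        }
    )
    rows.append(
        {
            "source": "Residuals",
            "df": df_err,
            "SS": ss_err,
            "MS": ms_err,
            "F": np.nan,
            "p": np.nan,
            "sig": "",
            "accumulated_pct": np.nan,
        }
    )
    cv = 100.0 * float(np.sqrt(ms_err)) / grand if grand > 0 else np.nan
    return AnovaTable(table=pd.DataFrame(rows), cv_percent=cv, grand_mean=grand)
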