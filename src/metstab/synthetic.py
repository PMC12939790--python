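"""Synthetic augmented-design MET generator with known ground truth.

The generator is the sampling counterpart of the AMMI model: plot yields
are built as

    Y_ij = μ + G_i + E_j + Σ_k λ_k γ_ik δ_jk + ρ_ij,

with centered Gaussian genotype and environment effects, an exact low-rank
interaction assembled from orthonormalized random score vectors carrying
prescribed λ² shares, and i.i.d. Gaussian plot noise.  Lines appear once
per environment; check genotypes are additive (zero interaction) by
default and are replicated across blocks within every environment, with
optional Gaussian block effects.

Because the interaction score vectors are built orthogonal to the constant
vector (and zero on planted-stable rows), the planted interaction is
exactly double-centered: at zero noise every estimator downstream recovers
its planted parameter exactly — λ shares from the AMMI fit, slopes from
joint regression, W² = 0 for planted-stable genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .met_io import Role, TrialRecord
from .ammi import svd_sign_convention

__all__ = ["SimulationSpec", "GroundTruth", "simulate_met", "simulate_fw"]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated trial.

    Defaults emulate the augmented layout of a small wheat MET: unreplicated
    lines plus four check cultivars in quadruplicate across four
    environments, yields on the t/ha scale.
    """

    g_lines: int = 40
    n_env: int = 4
    n_checks: int = 4
    reps_per_check: int = 4
    mu: float = 7.0
    sd_gen: float = 0.8
    sd_env: float = 1.5
    interaction_rank: int = 2
    lambda_shares: tuple[float, ...] = (0.6, 0.4)
    sd_gei: float = 0.5
    sd_noise: float = 0.3
    sd_block: float = 0.0
    planted_stable: int = 0
    planted_stable_advantage: float = 0.0
    planted_slopes: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_lines < 2 or self.n_env < 2:
            raise ValueError("need >= 2 lines and >= 2 environments")
        if min(self.sd_gen, self.sd_env, self.sd_gei, self.sd_noise, self.sd_block) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.interaction_rank > 0:
            if len(self.lambda_shares) != self.interaction_rank:
                raise ValueError("lambda_shares length must equal interaction_rank")
            if abs(sum(self.lambda_shares) - 1.0) > 1e-9 or min(self.lambda_shares) < 0:
                raise ValueError("lambda_shares must be non-negative and sum to 1")
            free_rows = self.g_lines - self.planted_stable
            if self.interaction_rank > min(free_rows - 1, self.n_env - 1):
                raise ValueError(
                    f"interaction_rank {self.interaction_rank} too high for "
                    f"{free_rows} interacting lines x {self.n_env} environments"
                )
        if not (0 <= self.planted_stable <= self.g_lines):
            raise ValueError("planted_stable out of range")
        if self.planted_slopes is not None and len(self.planted_slopes) != self.g_lines:
            raise ValueError("planted_slopes must have one entry per line")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator planted, for recovery checks."""

    mu: float
    genotype_effects: np.ndarray  # lines, centered
    environment_effects: np.ndarray  # centered
    interaction: np.ndarray  # lines x env, exactly double-centered
    singular_values: np.ndarray
    genotype_scores: np.ndarray  # unit-norm γ columns
    environment_scores: np.ndarray  # unit-norm δ columns
    lambda_shares: np.ndarray
    stable_genotypes: tuple[str, ...]
    slopes: np.ndarray | None = None
    line_ids: tuple[str, ...] = ()
    environment_ids: tuple[str, ...] = ()
    check_ids: tuple[str, ...] = ()
    check_effects: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _orthonormal_scores(rng: np.random.Generator, dim: int, rank: int,
                        zero_rows: np.ndarray | None = None) -> np.ndarray:
    """Rank orthonormal columns orthogonal to the constant vector, zero on
    ``zero_rows`` (and sum-zero over the remaining support)."""
    active = np.ones(dim, dtype=bool)
    if zero_rows is not None:
        active[zero_rows] = False
    m = int(active.sum())
    if rank > m - 1:
        raise ValueError("rank too high for the active support")
    raw = rng.standard_normal((m, rank))
    ones = np.ones(m) / np.sqrt(m)
    raw -= ones[:, None] * (ones @ raw)
    q, r = np.linalg.qr(raw)
    q *= np.sign(np.diag(r))  # deterministic QR sign
    out = np.zeros((dim, rank))
    out[active] = q
    return out


def _interaction(spec: SimulationSpec, rng: np.random.Generator):
    """Exact low-rank double-centered interaction with planted λ² shares.

    Total interaction SS is sd_gei² · g_lines · n_env (per-cell scale
    sd_gei); stable rows are identically zero.
    """
    g, n, r = spec.g_lines, spec.n_env, spec.interaction_rank
    if r == 0 or spec.sd_gei == 0:
        return np.zeros((g, n)), np.zeros(0), np.zeros((g, 0)), np.zeros((n, 0))
    zero_rows = np.arange(spec.planted_stable)
    gamma = _orthonormal_scores(rng, g, r, zero_rows)
    delta = _orthonormal_scores(rng, n, r)
    total_ss = spec.sd_gei**2 * g * n
    lam = np.sqrt(np.asarray(spec.lambda_shares) * total_ss)
    order = np.argsort(-lam)
    lam, gamma, delta = lam[order], gamma[:, order], delta[:, order]
    gamma, delta = svd_sign_convention(gamma, delta)
    return (gamma * lam) @ delta.T, lam, gamma, delta


def _emit_records(
    spec: SimulationSpec,
    cell_means: np.ndarray,
    check_effects: np.ndarray,
    env_effects: np.ndarray,
    rng: np.random.Generator,
):
    line_ids = tuple(f"L{i + 1:03d}" for i in range(spec.g_lines))
    env_ids = tuple(f"E{j + 1}" for j in range(spec.n_env))
    check_ids = tuple(f"CHK{c + 1}" for c in range(spec.n_checks))
    records: list[TrialRecord] = []
    for j, env in enumerate(env_ids):
        blocks = [f"B{b + 1}" for b in range(max(spec.reps_per_check, 1))]
        block_eff = rng.normal(0.0, spec.sd_block, size=len(blocks)) if spec.sd_block else np.zeros(len(blocks))
        for i, line in enumerate(line_ids):
            blk = blocks[i % len(blocks)]
            y = cell_means[i, j] + block_eff[i % len(blocks)] + rng.normal(0.0, spec.sd_noise)
            records.append(TrialRecord(env, line, blk, Role.LINE, max(y, 0.0)))
        if spec.n_checks:
            for b, blk in enumerate(blocks):
                for c, chk in enumerate(check_ids):
                    y = (
                        spec.mu
                        + check_effects[c]
                        + env_effects[j]
                        + block_eff[b]
                        + rng.normal(0.0, spec.sd_noise)
                    )
                    records.append(TrialRecord(env, chk, blk, Role.CHECK, max(y, 0.0)))
    return records, line_ids, env_ids, check_ids


def simulate_met(spec: SimulationSpec) -> tuple[list[TrialRecord], GroundTruth]:
    """Draw one augmented MET under the AMMI sampling model.

    Returns the plot records (lines once per cell, checks replicated in
    blocks) and the full ground truth.  Byte-identical for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    g, n = spec.g_lines, spec.n_env
    gen_eff = rng.normal(0.0, spec.sd_gen, size=g)
    gen_eff -= gen_eff.mean()
    if spec.planted_stable and spec.planted_stable_advantage:
        # yield bonus for the planted-stable lines (kept in the recorded truth)
        gen_eff[: spec.planted_stable] += spec.planted_stable_advantage
    env_eff = rng.normal(0.0, spec.sd_env, size=n)
    env_eff -= env_eff.mean()
    check_eff = rng.normal(0.0, spec.sd_gen, size=spec.n_checks)
    interaction, lam, gamma, delta = _interaction(spec, rng)
    cell_means = spec.mu + gen_eff[:, None] + env_eff[None, :] + interaction
    records, line_ids, env_ids, check_ids = _emit_records(
        spec, cell_means, check_eff, env_eff, rng
    )
    truth = GroundTruth(
        mu=spec.mu,
        genotype_effects=gen_eff,
        environment_effects=env_eff,
        interaction=interaction,
        singular_values=lam,
        genotype_scores=gamma,
        environment_scores=delta,
        lambda_shares=np.asarray(spec.lambda_shares if spec.interaction_rank else ()),
        stable_genotypes=tuple(line_ids[: spec.planted_stable]),
        line_ids=line_ids,
        environment_ids=env_ids,
        check_ids=check_ids,
        check_effects=check_eff,
    )
    return records, truth


def simulate_fw(spec: SimulationSpec) -> tuple[list[TrialRecord], GroundTruth]:
    """Finlay–Wilkinson sampling model: X_ij = X̄_i + b_i (E_j − Ē) + noise.

    Planted slopes are rescaled to mean 1 (the empirical environmental
    index forces mean slope 1, so only mean-1 slope sets are recoverable).
    At zero noise ``joint_regression`` recovers every slope exactly.
    """
    if spec.planted_slopes is None:
        raise ValueError("simulate_fw needs planted_slopes")
    rng = np.random.default_rng(spec.seed)
    g, n = spec.g_lines, spec.n_env
    slopes = np.asarray(spec.planted_slopes, dtype=float)
    mean_slope = slopes.mean()
    if mean_slope == 0:
        raise ValueError("planted slopes must not average to zero")
    slopes = slopes / mean_slope
    gen_eff = rng.normal(0.0, spec.sd_gen, size=g)
    gen_eff -= gen_eff.mean()
    env_eff = rng.normal(0.0, spec.sd_env, size=n)
    env_eff -= env_eff.mean()
    if np.allclose(env_eff, 0.0):
        raise ValueError("degenerate environment spread: sd_env must be > 0")
    check_eff = rng.normal(0.0, spec.sd_gen, size=spec.n_checks)
    cell_means = spec.mu + gen_eff[:, None] + slopes[:, None] * env_eff[None, :]
    records, line_ids, env_ids, check_ids = _emit_records(
        spec, cell_means, check_eff, env_eff, rng
    )
    truth = GroundTruth(
        mu=spec.mu,
        genotype_effects=gen_eff,
        environment_effects=env_eff,
        interaction=(slopes[:, None] - 1.0) * env_eff[None, :],
        singular_values=np.zeros(0),
        genotype_scores=np.zeros((g, 0)),
        environment_scores=np.zeros((n, 0)),
        lambda_shares=np.zeros(0),
        stable_genotypes=(),
        slopes=slopes,
        line_ids=line_ids,
        environment_ids=env_ids,
        check_ids=check_ids,
        check_effects=check_eff,
    )
    return records, truth
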