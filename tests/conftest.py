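"""Shared fixtures: small random matrices and synthetic trials."""

from __future__ import annotations

import numpy as np
import pytest

from metstab import METMatrix, Role, SimulationSpec, TrialRecord, simulate_met, to_matrix


def random_matrix(g: int, n: int, seed: int, mu: float = 7.0) -> METMatrix:
    rng = np.random.default_rng(seed)
    values = mu + rng.normal(0.0, 1.0, size=(g, n))
    return METMatrix(
        values,
        tuple(f"G{i + 1}" for i in range(g)),
        tuple(f"E{j + 1}" for j in range(n)),
    )


@pytest.fixture
def matrix_5x4() -> METMatrix:
    return random_matrix(5, 4, seed=42)


@pytest.fixture
def matrix_12x6() -> METMatrix:
    return random_matrix(12, 6, seed=7)


@pytest.fixture
def line_records() -> list[TrialRecord]:
    """3 lines x 2 environments, one plot each."""
    vals = {("G1", "E1"): 5.0, ("G1", "E2"): 6.0,
            ("G2", "E1"): 7.0, ("G2", "E2"): 8.0,
            ("G3", "E1"): 4.0, ("G3", "E2"): 9.0}
    return [
        TrialRecord(env, g, "B1", Role.LINE, y) for (g, env), y in vals.items()
    ]


@pytest.fixture
def augmented_records() -> list[TrialRecord]:
    """Noisy augmented MET: 15 lines + 3 checks x 3 blocks x 4 envs."""
    spec = SimulationSpec(
        g_lines=15, n_env=4, n_checks=3, reps_per_check=3,
        interaction_rank=2, lambda_shares=(0.7, 0.3), sd_gei=0.4,
        sd_noise=0.25, seed=11,
    )
    records, _ = simulate_met(spec)
    return records


@pytest.fixture
def augmented_matrix(augmented_records) -> METMatrix:
    return to_matrix([r for r in augmented_records if r.role is Role.LINE])
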