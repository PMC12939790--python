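"""Trial-data ingestion and the genotype-by-environment mean matrix.

A multi-environment trial (MET) records plot yields of genotypes grown in
several environments.  In an augmented design the test lines are
unreplicated while a handful of check cultivars are replicated in blocks
within each environment.  Every downstream stability statistic operates on
the genotype-by-environment cell-mean matrix ``X`` with margins

* ``X̄_i``  — genotype means (rows),
* ``X̄_j``  — environment means (columns), also called the environmental
  index ``E_j`` used by joint-regression stability,
* ``X̄``    — the grand mean.

This module reads/writes long-format plot tables and wide matrices,
validates them, and builds :class:`METMatrix`.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "TrialRecord",
    "METMatrix",
    "RunConfig",
    "MetIOError",
    "FormatError",
    "ValidationError",
    "read_long_table",
    "read_matrix",
    "write_matrix",
    "to_matrix",
    "environmental_index",
    "records_to_frame",
    "load_mock_experiment",
]

#: Canonical column names of the long format; mapped case-insensitively.
LONG_COLUMNS = ("environment", "genotype", "block", "role", "yield")


class MetIOError(Exception):
    """Base error for trial-data input problems."""


class FormatError(MetIOError):
    """Malformed file: missing columns, bad values, duplicate cells."""


class ValidationError(MetIOError):
    """Structurally valid data that violates a completeness invariant."""


class Role(str, enum.Enum):
    """Entry role in the augmented design."""

    CHECK = "check"
    LINE = "line"


@dataclass(frozen=True)
class TrialRecord:
    """One plot observation: yield of a genotype in one block of one
    environment, in t/ha."""

    environment: str
    genotype: str
    block: str
    role: Role
    yield_: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.yield_) or self.yield_ < 0:
            raise ValueError(
                f"yield must be finite and non-negative, got {self.yield_!r} "
                f"for genotype {self.genotype!r} in {self.environment!r}"
            )


class MissingPolicy(str, enum.Enum):
    ERROR = "error"
    IMPUTE_ENV_MEAN = "impute_env_mean"


class ShuklaMode(str, enum.Enum):
    """Which stability-variance estimator feeds the ranking.

    ``paper_literal`` divides the genotype's interaction sum of squares by
    n−1; ``classical`` is Shukla's (1972) unbiased variance-component
    estimator.  Both are always reported side by side in tables.
    """

    PAPER_LITERAL = "paper_literal"
    CLASSICAL = "classical"


@dataclass
class RunConfig:
    """Plumbing options shared across the pipeline."""

    missing_policy: MissingPolicy = MissingPolicy.ERROR
    check_adjustment: bool = False
    shukla_mode: ShuklaMode = ShuklaMode.PAPER_LITERAL
    sid_include_yield: bool = False
    linkage: str = "ward"
    distance: str = "euclidean"
    seed: int = 0
    output_dir: Path = Path("met-stab-output")

    def __post_init__(self) -> None:
        self.missing_policy = MissingPolicy(self.missing_policy)
        self.shukla_mode = ShuklaMode(self.shukla_mode)
        self.output_dir = Path(self.output_dir)

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class METMatrix:
    """Complete genotype-by-environment cell-mean matrix with margins.

    ``values[i, j]`` is the mean yield of genotype ``genotype_ids[i]`` in
    environment ``environment_ids[j]`` (t/ha).  Margins are arithmetic
    means; ``environment_means`` doubles as the environmental index.
    """

    values: np.ndarray
    genotype_ids: tuple[str, ...]
    environment_ids: tuple[str, ...]
    imputed: tuple[tuple[str, str], ...] = ()
    unit: str = "t/ha"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "genotype_ids", tuple(map(str, self.genotype_ids)))
        object.__setattr__(self, "environment_ids", tuple(map(str, self.environment_ids)))
        g, n = values.shape
        if g < 2 or n < 2:
            raise ValidationError(f"need at least 2 genotypes and 2 environments, got {g}x{n}")
        if len(self.genotype_ids) != g or len(self.environment_ids) != n:
            raise ValidationError("label lengths do not match matrix shape")
        if len(set(self.genotype_ids)) != g:
            raise ValidationError("duplicate genotype labels")
        if len(set(self.environment_ids)) != n:
            raise ValidationError("duplicate environment labels")
        if not np.all(np.isfinite(values)):
            bad = [
                (self.genotype_ids[i], self.environment_ids[j])
                for i, j in zip(*np.nonzero(~np.isfinite(values)))
            ]
            raise ValidationError(f"non-finite cells after validation: {bad}")

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_environments(self) -> int:
        return self.values.shape[1]

    @property
    def genotype_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    @property
    def environment_means(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.values.mean())

    def row(self, genotype: str) -> np.ndarray:
        try:
            i = self.genotype_ids.index(str(genotype))
        except ValueError:
            raise KeyError(f"unknown genotype {genotype!r}") from None
        return self.values[i]

    def interaction_residuals(self) -> np.ndarray:
        """Double-centered matrix Z_ij = X_ij − X̄_i − X̄_j + X̄ (the GEI part)."""
        return (
            self.values
            - self.genotype_means[:, None]
            - self.environment_means[None, :]
            + self.grand_mean
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.genotype_ids), columns=list(self.environment_ids)
        )


# ---------------------------------------------------------------------------
# long-format reading


def _resolve_columns(header: Sequence[str], mapping: Mapping[str, str] | None) -> dict[str, int]:
    """Map canonical field names to column indices, case-insensitively."""
    mapping = {k.lower(): v.lower() for k, v in (mapping or {}).items()}
    lowered = [h.strip().lower() for h in header]
    out: dict[str, int] = {}
    for name in LONG_COLUMNS:
        wanted = mapping.get(name, name)
        if wanted not in lowered:
            raise FormatError(f"missing required column {wanted!r} (for field {name!r})")
        out[name] = lowered.index(wanted)
    return out


def read_long_table(
    path: str | Path,
    column_mapping: Mapping[str, str] | None = None,
    dialect: str | csv.Dialect = "excel",
) -> list[TrialRecord]:
    """Read a long-format plot-yield CSV into trial records.

    Expects columns environment, genotype, block, role, yield (any order,
    case-insensitive; ``column_mapping`` renames them).  Unreplicated lines
    must appear at most once per (genotype, environment); checks may repeat.
    """
    path = Path(path)
    records: list[TrialRecord] = []
    seen_line_cells: set[tuple[str, str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, dialect=dialect)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        cols = _resolve_columns(header, column_mapping)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                raw_role = row[cols["role"]].strip().lower()
                role = Role(raw_role)
            except (ValueError, IndexError):
                raise FormatError(
                    f"{path}:{lineno}: role must be 'check' or 'line', got {row!r}"
                ) from None
            try:
                yield_ = float(row[cols["yield"]])
            except (ValueError, IndexError):
                raise FormatError(
                    f"{path}:{lineno}: non-numeric yield {row[cols['yield']]!r}"
                ) from None
            rec = TrialRecord(
                environment=row[cols["environment"]].strip(),
                genotype=row[cols["genotype"]].strip(),
                block=row[cols["block"]].strip(),
                role=role,
                yield_=yield_,
            )
            if rec.role is Role.LINE:
                cell = (rec.genotype, rec.environment)
                if cell in seen_line_cells:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate line record for genotype "
                        f"{rec.genotype!r} in environment {rec.environment!r}"
                    )
                seen_line_cells.add(cell)
            records.append(rec)
    return records


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of a record collection."""
    return pd.DataFrame(
        [
            {
                "environment": r.environment,
                "genotype": r.genotype,
                "block": r.block,
                "role": r.role.value,
                "yield": r.yield_,
            }
            for r in records
        ]
    )


def write_long_table(records: Iterable[TrialRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# matrix construction


def _ordered_unique(items: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for it in items:
        seen.setdefault(it, None)
    return list(seen)


def to_matrix(
    records: Sequence[TrialRecord],
    config: RunConfig | None = None,
    include_checks: bool = True,
) -> METMatrix:
    """Build the genotype-by-environment cell-mean matrix from plot records.

    Each cell is the mean of all records for that (genotype, environment);
    checks therefore contribute replicate means.  Order of genotypes and
    environments follows first appearance in the input.  With
    ``config.check_adjustment`` the line plots are first adjusted by their
    block's check deviation (value − (block check mean − environment check
    mean)), the standard augmented-design correction.

    Missing cells raise :class:`ValidationError` under the default policy or
    are imputed with the environment mean (and flagged) under
    ``impute_env_mean``.
    """
    config = config or RunConfig()
    if not records:
        raise ValidationError("no records")
    recs = list(records)
    if not include_checks:
        recs = [r for r in recs if r.role is Role.LINE]
        if not recs:
            raise ValidationError("no line records")

    adjusted = {id(r): r.yield_ for r in recs}
    if config.check_adjustment:
        checks = [r for r in records if r.role is Role.CHECK]
        if not checks:
            raise ValidationError("check_adjustment requested but no check records present")
        env_check_mean: dict[str, float] = {}
        block_check_mean: dict[tuple[str, str], float] = {}
        cf = records_to_frame(checks)
        for env, sub in cf.groupby("environment"):
            env_check_mean[str(env)] = float(sub["yield"].mean())
        for (env, blk), sub in cf.groupby(["environment", "block"]):
            block_check_mean[(str(env), str(blk))] = float(sub["yield"].mean())
        for r in recs:
            if r.role is Role.LINE:
                key = (r.environment, r.block)
                if key not in block_check_mean:
                    raise ValidationError(
                        f"no checks in block {r.block!r} of environment "
                        f"{r.environment!r}; cannot adjust"
                    )
                adjusted[id(r)] = r.yield_ - (
                    block_check_mean[key] - env_check_mean[r.environment]
                )

    genotypes = _ordered_unique(r.genotype for r in recs)
    environments = _ordered_unique(r.environment for r in recs)
    g, n = len(genotypes), len(environments)
    gi = {gt: i for i, gt in enumerate(genotypes)}
    ej = {env: j for j, env in enumerate(environments)}

    sums = np.zeros((g, n))
    counts = np.zeros((g, n), dtype=int)
    for r in recs:
        i, j = gi[r.genotype], ej[r.environment]
        sums[i, j] += adjusted[id(r)]
        counts[i, j] += 1

    values = np.full((g, n), np.nan)
    np.divide(sums, counts, out=values, where=counts > 0)

    imputed: list[tuple[str, str]] = []
    if np.any(counts == 0):
        empty = [(genotypes[i], environments[j]) for i, j in zip(*np.nonzero(counts == 0))]
        if config.missing_policy is MissingPolicy.ERROR:
            raise ValidationError(f"empty cells (genotype, environment): {empty}")
        col_means = np.nanmean(values, axis=0)
        for i, j in zip(*np.nonzero(counts == 0)):
            values[i, j] = col_means[j]
            imputed.append((genotypes[i], environments[j]))

    return METMatrix(values, tuple(genotypes), tuple(environments), tuple(imputed))


def environmental_index(matrix: METMatrix) -> np.ndarray:
    """Environmental index E_j: mean yield of all genotypes in environment j."""
    return matrix.environment_means


# ---------------------------------------------------------------------------
# wide-matrix round trip


def read_matrix(path: str | Path) -> METMatrix:
    """Read a wide genotype-by-environment CSV: genotype labels in column 1,
    environment labels in the header."""
    df = pd.read_csv(path, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix cell: {exc}") from None
    if np.isnan(values).any():
        raise ValidationError(f"{path}: matrix contains missing cells")
    return METMatrix(values, tuple(map(str, df.index)), tuple(map(str, df.columns)))


def write_matrix(matrix: METMatrix, path: str | Path, sig_digits: int = 6) -> None:
    """Write a wide CSV at ``sig_digits`` significant digits (default 6)."""
    df = matrix.to_frame()
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("genotype," + ",".join(matrix.environment_ids) + "\n")
        for gt, row in zip(matrix.genotype_ids, df.to_numpy()):
            fh.write(gt + "," + ",".join(f"{v:.{sig_digits}g}" for v in row) + "\n")


def load_mock_experiment() -> list[TrialRecord]:
    """Packaged synthetic mock experiment: 20 lines + 4 checks in
    quadruplicate across 4 environments, generated by
    :mod:`metstab.synthetic` at a fixed seed and frozen as CSV.

    Purely synthetic demonstration data — no field measurements.
    """
    path = Path(__file__).parent / "data" / "mock_experiment.csv"
    return read_long_table(path)
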