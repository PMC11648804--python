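"""Data model, validation and CSV I/O for long-format multi-environment trials.

A *trial* here is a set of plot-level yield records: each plot carries a
genotype, a season, a cropping system, a replication number, and one or more
trait values in t·ha⁻¹ (e.g. CWH = cob weight with husk, GY = grain yield).
An *environment* is one season × cropping-system combination, labelled
C1, C2, ... in a deterministic order (sorted by season, then system).

The two derived containers are :class:`TrialTable` (validated long-format
plot data) and :class:`MeansMatrix` (the genotype × environment cell-mean
table that AMMI and GGE decompose).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "IncompleteDataError",
    "EnvironmentKey",
    "TrialTable",
    "MeansMatrix",
    "DEFAULT_SCHEMA",
    "read_trial_csv",
    "write_trial_csv",
    "cell_means",
]

#: Default CSV column names; override any entry via the ``schema`` mapping.
DEFAULT_SCHEMA: dict[str, object] = {
    "genotype": "genotype",
    "season": "season",
    "system": "system",
    "rep": "rep",
    "traits": None,  # None = every remaining numeric column is a trait
}

#: Number of significant digits used when writing derived tables.
FLOAT_DIGITS = 6


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class ValidationError(ValueError):
    """The data violate a trial-table invariant (duplicates, negatives...)."""


class IncompleteDataError(ValueError):
    """A genotype × environment cell required for an analysis is missing."""

    def __init__(self, message: str, missing: list[tuple[str, str]] | None = None):
        super().__init__(message)
        self.missing = missing or []


@dataclass(frozen=True, order=True)
class EnvironmentKey:
    """One test environment: a season × cropping-system combination."""

    season: str
    system: str
    label: str = field(compare=False, default="")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label or f"{self.season}/{self.system}"


def _environment_keys(df: pd.DataFrame) -> list[EnvironmentKey]:
    """Deterministic environment labelling: sort by season then system."""
    combos = sorted(set(zip(df["season"], df["system"])))
    return [
        EnvironmentKey(season=s, system=c, label=f"C{i + 1}")
        for i, (s, c) in enumerate(combos)
    ]


class TrialTable:
    """Validated long-format plot observations.

    Parameters
    ----------
    data
        DataFrame with columns ``genotype``, ``season``, ``system``, ``rep``
        plus one numeric column per trait.
    traits
        Names of the trait columns. If omitted, every column other than the
        four key columns is treated as a trait.
    allow_unbalanced
        If False (default), the replication set must be identical in every
        genotype × environment cell.

    Raises
    ------
    ValidationError
        On duplicate (genotype, season, system, rep) keys, negative or
        non-finite trait values, or (unless ``allow_unbalanced``) unequal
        replication across cells.
    """

    KEY_COLUMNS = ("genotype", "season", "system", "rep")

    def __init__(
        self,
        data: pd.DataFrame,
        traits: Sequence[str] | None = None,
        allow_unbalanced: bool = False,
    ):
        missing = [c for c in self.KEY_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if traits is None:
            traits = [c for c in data.columns if c not in self.KEY_COLUMNS]
        if not traits:
            raise SchemaError("no trait columns found")
        absent = [t for t in traits if t not in data.columns]
        if absent:
            raise SchemaError(f"trait column(s) not in table: {', '.join(absent)}")

        df = data.loc[:, list(self.KEY_COLUMNS) + list(traits)].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["season"] = df["season"].astype(str)
        df["system"] = df["system"].astype(str)
        try:
            df["rep"] = df["rep"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"replication column is not integer: {exc}") from exc
        if (df["rep"] < 1).any():
            row = int(df.index[df["rep"] < 1][0])
            raise ValidationError(f"rep must be >= 1 (row {row})")

        for t in traits:
            col = pd.to_numeric(df[t], errors="coerce")
            bad = ~np.isfinite(col.to_numpy(dtype=float))
            if bad.any():
                row = int(df.index[bad][0])
                raise ValidationError(
                    f"trait {t!r} has a non-numeric or non-finite value at row {row}"
                )
            if (col < 0).any():
                row = int(df.index[col < 0][0])
                raise ValidationError(f"trait {t!r} is negative at row {row}")
            df[t] = col.astype(float)

        dup = df.duplicated(subset=list(self.KEY_COLUMNS))
        if dup.any():
            first = df.loc[dup.idxmax(), list(self.KEY_COLUMNS)].tolist()
            raise ValidationError(
                f"duplicate (genotype, season, system, rep) key: {tuple(first)}"
            )

        if not allow_unbalanced:
            rep_sets = df.groupby(["genotype", "season", "system"], sort=False)[
                "rep"
            ].agg(frozenset)
            if rep_sets.nunique() > 1:
                raise ValidationError(
                    "replication sets differ across genotype × environment cells; "
                    "pass allow_unbalanced=True to accept"
                )

        self.data = df.reset_index(drop=True)
        self.traits = list(traits)
        self.allow_unbalanced = allow_unbalanced
        self.environments = _environment_keys(df)
        self.genotypes = sorted(df["genotype"].unique())
        self.reps = sorted(df["rep"].unique())
        env_label = {(e.season, e.system): e.label for e in self.environments}
        self.data["env"] = [
            env_label[(s, c)] for s, c in zip(self.data["season"], self.data["system"])
        ]

    # ------------------------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    @property
    def seasons(self) -> list[str]:
        return sorted(self.data["season"].unique())

    @property
    def systems(self) -> list[str]:
        return sorted(self.data["system"].unique())

    def is_balanced(self) -> bool:
        counts = self.data.groupby(["genotype", "env"]).size()
        return counts.nunique() == 1 and len(counts) == self.n_genotypes * self.n_environments

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (
            f"TrialTable({self.n_genotypes} genotypes × {self.n_environments} "
            f"environments, {len(self)} plots, traits={self.traits})"
        )


@dataclass
class MeansMatrix:
    """Genotype × environment cell means for one trait.

    ``values`` is indexed by genotype ID with one column per environment
    label; ``environments`` preserves the season/system identity of each
    column; ``n_reps`` is the number of replicates averaged per cell.
    """

    trait: str
    values: pd.DataFrame
    environments: list[EnvironmentKey]
    n_reps: int

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def env_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def grand_mean(self) -> float:
        return float(self.values.to_numpy().mean())

    def genotype_means(self) -> pd.Series:
        return self.values.mean(axis=1)

    def environment_means(self) -> pd.Series:
        return self.values.mean(axis=0)


# ----------------------------------------------------------------------
# CSV I/O


def read_trial_csv(
    path: str | Path,
    schema: Mapping[str, object] | None = None,
    allow_unbalanced: bool = False,
) -> TrialTable:
    """Read a long-format trial CSV into a validated :class:`TrialTable`.

    ``schema`` maps logical names (genotype, season, system, rep, traits) to
    the column names used in the file; ``traits`` may be a list of column
    names or None to take every remaining column as a trait.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    resolved = dict(DEFAULT_SCHEMA)
    if schema:
        resolved.update(schema)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty file: {path}") from exc
    rename = {}
    for logical in ("genotype", "season", "system", "rep"):
        col = resolved[logical]
        if col not in raw.columns:
            raise SchemaError(f"column {col!r} (for {logical}) not found in {path}")
        rename[col] = logical
    traits = resolved.get("traits")
    if traits is not None:
        traits = list(traits)
        for t in traits:
            if t not in raw.columns:
                raise SchemaError(f"trait column {t!r} not found in {path}")
    df = raw.rename(columns=rename)
    return TrialTable(df, traits=traits, allow_unbalanced=allow_unbalanced)


def write_trial_csv(table: TrialTable, path: str | Path) -> None:
    """Write a TrialTable back to CSV in normalized column order."""
    cols = list(TrialTable.KEY_COLUMNS) + table.traits
    out = table.data.loc[:, cols].sort_values(list(TrialTable.KEY_COLUMNS))
    out.to_csv(path, index=False, float_format=f"%.{FLOAT_DIGITS}g")


def write_table_csv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a derived table with the package-wide float format."""
    df.to_csv(path, index=index, float_format=f"%.{FLOAT_DIGITS}g")


# ----------------------------------------------------------------------
# Cell means


def cell_means(
    table: TrialTable,
    trait: str,
    impute_missing: bool = False,
) -> MeansMatrix:
    """Average plot values over replicates into a genotype × environment table.

    Missing cells raise :class:`IncompleteDataError` unless
    ``impute_missing`` is set, in which case each absent cell is filled with
    genotype mean + environment mean − grand mean (the additive expectation).
    """
    if trait not in table.traits:
        raise SchemaError(f"unknown trait {trait!r}; table has {table.traits}")
    labels = [e.label for e in table.environments]
    means = (
        table.data.groupby(["genotype", "env"])[trait]
        .mean()
        .unstack("env")
        .reindex(index=table.genotypes, columns=labels)
    )
    if means.isna().any().any():
        missing = [
            (g, e) for g in means.index for e in means.columns if pd.isna(means.at[g, e])
        ]
        if not impute_missing:
            raise IncompleteDataError(
                f"missing genotype × environment cell(s): {missing[:10]}"
                + ("..." if len(missing) > 10 else ""),
                missing=missing,
            )
        grand = float(np.nanmean(means.to_numpy()))
        g_mean = means.mean(axis=1, skipna=True)
        e_mean = means.mean(axis=0, skipna=True)
        for g, e in missing:
            means.at[g, e] = g_mean[g] + e_mean[e] - grand
    n_reps = int(round(len(table.data) / means.size)) if means.size else 0
    return MeansMatrix(
        trait=trait,
        values=means,
        environments=list(table.environments),
        n_reps=n_reps,
    )
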