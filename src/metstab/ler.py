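"""Land Equivalent Ratio (LER) for intercropping systems.

For a system with component crops i = 1..a, where ``IC_i`` is a crop's
mean yield grown in the intercrop and ``C_i`` its mean yield grown as a
sole crop on the same land,

    LER = sum_i IC_i / C_i .

LER > 1 means the intercrop needs less land than the equivalent set of
sole crops — a land-use (economic) advantage; LER exactly 1 is neutral
and counts as not favorable.  LER is computed per genotype × season ×
intercropping system, from either explicit component records or a trial
table (maize-side ratio) plus an optional companion-crop CSV, since a
maize trial records only the maize trait.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import IncompleteDataError, SchemaError, TrialTable

__all__ = [
    "ler",
    "ler_table",
    "favorability_count",
    "ler_from_trial",
    "read_companion_csv",
]

COMPONENT_COLUMNS = ["genotype", "season", "system", "crop", "intercrop_mean", "sole_mean"]


def ler(components: pd.DataFrame) -> pd.DataFrame:
    """LER per genotype × season × system from component crop records.

    ``components`` needs columns genotype, season, system, crop,
    intercrop_mean, sole_mean (one row per component crop).  Returns one
    row per (genotype, season, system) with ``LER`` and ``favorable``
    (strictly > 1).
    """
    missing = [c for c in COMPONENT_COLUMNS if c not in components.columns]
    if missing:
        raise SchemaError(f"component table missing column(s): {', '.join(missing)}")
    if components.empty:
        raise IncompleteDataError("component table is empty")
    bad = components[components["sole_mean"] <= 0]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"sole-crop mean must be > 0: crop {row['crop']!r} for genotype "
            f"{row['genotype']!r} ({row['season']}, {row['system']})"
        )
    if (components["intercrop_mean"] < 0).any():
        raise ValueError("intercrop means must be >= 0")
    parts = components.assign(
        partial=components["intercrop_mean"] / components["sole_mean"]
    )
    # every (genotype, season, system) must carry the same component crops
    crops = parts.groupby(["season", "system"])["crop"].agg(lambda s: frozenset(s))
    per_geno = parts.groupby(["genotype", "season", "system"])["crop"].agg(
        lambda s: frozenset(s)
    )
    for (g, se, sy), cs in per_geno.items():
        expected = crops[(se, sy)]
        if cs != expected:
            raise IncompleteDataError(
                f"genotype {g!r} in ({se}, {sy}) is missing component crop(s) "
                f"{sorted(expected - cs)}"
            )
    out = (
        parts.groupby(["genotype", "season", "system"], as_index=False)["partial"]
        .sum()
        .rename(columns={"partial": "LER"})
    )
    out["favorable"] = out["LER"] > 1.0
    return out


def ler_table(values: pd.DataFrame) -> pd.DataFrame:
    """Wrap precomputed LER values (columns ..., ``LER``) with the
    favorability flag; accepts any extra stratifying columns (trait...)."""
    if "LER" not in values.columns:
        raise SchemaError("expected a 'LER' column")
    if (values["LER"] < 0).any():
        raise ValueError("LER values must be >= 0")
    out = values.copy()
    out["favorable"] = out["LER"] > 1.0
    return out


def favorability_count(table: pd.DataFrame, **strata) -> int:
    """Number of genotypes with LER > 1 in one stratum.

    ``strata`` are column=value filters, e.g. ``season="2", system="IC2",
    trait="GY"``.  Raises ``KeyError`` if the stratum selects no rows.
    """
    sub = table
    for col, val in strata.items():
        if col not in sub.columns:
            raise KeyError(f"no column {col!r} in LER table")
        sub = sub[sub[col].astype(str) == str(val)]
    if sub.empty:
        raise KeyError(f"no LER rows match stratum {strata}")
    if "favorable" in sub.columns:
        return int(sub["favorable"].sum())
    return int((sub["LER"] > 1.0).sum())


def read_companion_csv(path: str | Path) -> pd.DataFrame:
    """Companion-crop component records (soybean, sweet potato, ...)."""
    df = pd.read_csv(path)
    missing = [c for c in COMPONENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"companion CSV missing column(s): {', '.join(missing)}")
    for col in ("genotype", "season", "system", "crop"):
        df[col] = df[col].astype(str)
    return df


def ler_from_trial(
    table: TrialTable,
    trait: str,
    sole_system: str = "sole",
    companion: pd.DataFrame | None = None,
    maize_only: bool = False,
) -> pd.DataFrame:
    """LER from a maize trial table, optionally adding companion crops.

    The maize component of each intercrop system is the genotype's trait
    mean in that system divided by its mean in the sole-crop system of the
    same season.  Companion components (the trial table holds only the
    maize trait) come from ``companion`` rows matched by genotype, season
    and system; with ``maize_only`` (or no companion data) the result is
    the maize partial LER alone.
    """
    if trait not in table.traits:
        raise SchemaError(f"unknown trait {trait!r}; table has {table.traits}")
    systems = table.systems
    if sole_system not in systems:
        raise SchemaError(f"sole system {sole_system!r} not in table systems {systems}")
    inter_systems = [s for s in systems if s != sole_system]
    means = (
        table.data.groupby(["genotype", "season", "system"])[trait]
        .mean()
        .rename("mean")
        .reset_index()
    )
    sole = means[means["system"] == sole_system].set_index(["genotype", "season"])["mean"]
    rows = []
    for sys_name in inter_systems:
        sub = means[means["system"] == sys_name]
        for _, rec in sub.iterrows():
            key = (rec["genotype"], rec["season"])
            if key not in sole.index:
                raise IncompleteDataError(
                    f"no sole-crop mean for genotype {key[0]!r} in season {key[1]!r}"
                )
            c_sole = float(sole[key])
            if c_sole <= 0:
                raise ValueError(
                    f"sole-crop mean is zero for genotype {key[0]!r}, season {key[1]!r}"
                )
            rows.append(
                {
                    "genotype": rec["genotype"],
                    "season": rec["season"],
                    "system": sys_name,
                    "crop": "maize",
                    "intercrop_mean": float(rec["mean"]),
                    "sole_mean": c_sole,
                }
            )
    comp = pd.DataFrame(rows)
    if companion is not None and not maize_only:
        comp = pd.concat([comp, companion[COMPONENT_COLUMNS]], ignore_index=True)
    return ler(comp)
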