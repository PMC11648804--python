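"""Combined analysis of variance for balanced multi-environment trials.

The model partitions plot-level variation in a g genotypes × s seasons ×
c cropping-systems × r replicates design into

    Rep(within environment), S, C, S×C, G, G×S, G×C, G×S×C, Error

where an environment is one season × system combination and replication is
nested in environment.  All sums of squares are the classical balanced-
design marginal-mean quantities; the residual pools everything not
explained by the listed effects and is the single error stratum against
which F ratios are formed by default (a flag switches the environmental
effects S, C and S×C to the replication-within-environment stratum for the
stricter mixed-model convention).

Descriptives reported alongside the table: grand mean, min, max, plot-level
SD and the coefficient of variation CV% = 100·sqrt(MS_error)/grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SchemaError, TrialTable, ValidationError

__all__ = ["AnovaTable", "combined_anova", "pct_ss", "cv_percent"]

SOURCE_ORDER = [
    "Rep",
    "Season",
    "System",
    "Season:System",
    "Genotype",
    "Genotype:Season",
    "Genotype:System",
    "Genotype:Season:System",
    "Error",
    "Total",
]


@dataclass
class AnovaTable:
    """ANOVA rows plus the trait's descriptive statistics.

    ``rows`` has columns source, df, SS, MS, F, p, pct_SS (F and p are NaN
    for Rep, Error and Total).
    """

    trait: str
    rows: pd.DataFrame
    grand_mean: float
    min: float
    max: float
    sd: float
    cv_percent: float

    def __getitem__(self, source: str) -> pd.Series:
        hit = self.rows[self.rows["source"] == source]
        if hit.empty:
            raise KeyError(f"unknown ANOVA source {source!r}")
        return hit.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        """Table plus footer rows for the descriptive statistics."""
        footer = pd.DataFrame(
            {
                "source": ["Mean", "Min", "Max", "SD", "CV%"],
                "SS": [self.grand_mean, self.min, self.max, self.sd, self.cv_percent],
            }
        )
        return pd.concat([self.rows, footer], ignore_index=True)


def _cell_ss(df: pd.DataFrame, y: str, factors: list[str], grand: float) -> float:
    """Between-cell SS for the crossing of ``factors``: Σ n_cell (ȳ_cell − ȳ)²."""
    g = df.groupby(factors, observed=True)[y]
    means = g.mean()
    counts = g.size()
    return float((counts * (means - grand) ** 2).sum())


def combined_anova(
    table: TrialTable,
    trait: str,
    env_effects_against_rep: bool = False,
) -> AnovaTable:
    """Combined ANOVA of a balanced trial for one trait.

    Parameters
    ----------
    table
        Balanced complete TrialTable.
    trait
        Trait column to analyse.
    env_effects_against_rep
        If True, test Season, System and Season×System against the
        replication-within-environment mean square instead of the pooled
        error (mixed-model convention for environmental effects).

    Raises
    ------
    SchemaError
        If the trait is not present.
    ValidationError
        If the table is not balanced and complete (use the cell-mean
        imputation option in :func:`metstab.core.cell_means` first, or
        collect the missing plots).
    """
    if trait not in table.traits:
        raise SchemaError(f"unknown trait {trait!r}; table has {table.traits}")
    df = table.data
    g = table.n_genotypes
    s = len(table.seasons)
    c = len(table.systems)
    counts = df.groupby(["genotype", "season", "system"]).size()
    if counts.nunique() != 1 or len(counts) != g * s * c:
        raise ValidationError(
            "combined_anova requires a balanced complete table; impute missing "
            "cells first (cell_means(..., impute_missing=True)) or supply "
            "complete data"
        )
    r = int(counts.iloc[0])
    n = len(df)
    y = df[trait].to_numpy(dtype=float)
    grand = float(y.mean())
    ss_total = float(((y - grand) ** 2).sum())

    ss_s = _cell_ss(df, trait, ["season"], grand)
    ss_c = _cell_ss(df, trait, ["system"], grand)
    ss_sc = _cell_ss(df, trait, ["season", "system"], grand) - ss_s - ss_c
    ss_g = _cell_ss(df, trait, ["genotype"], grand)
    ss_gs = _cell_ss(df, trait, ["genotype", "season"], grand) - ss_g - ss_s
    ss_gc = _cell_ss(df, trait, ["genotype", "system"], grand) - ss_g - ss_c
    ss_gsc = (
        _cell_ss(df, trait, ["genotype", "season", "system"], grand)
        - ss_g - ss_s - ss_c - ss_gs - ss_gc - ss_sc
    )
    # replication nested in environment: env×rep cell SS minus env cell SS
    ss_env = ss_s + ss_c + ss_sc
    ss_rep = _cell_ss(df, trait, ["env", "rep"], grand) - ss_env
    ss_err = ss_total - (ss_rep + ss_env + ss_g + ss_gs + ss_gc + ss_gsc)
    ss_err = max(ss_err, 0.0)

    dfs = {
        "Rep": s * c * (r - 1),
        "Season": s - 1,
        "System": c - 1,
        "Season:System": (s - 1) * (c - 1),
        "Genotype": g - 1,
        "Genotype:Season": (g - 1) * (s - 1),
        "Genotype:System": (g - 1) * (c - 1),
        "Genotype:Season:System": (g - 1) * (s - 1) * (c - 1),
    }
    dfs["Error"] = n - 1 - sum(dfs.values())
    sss = {
        "Rep": ss_rep,
        "Season": ss_s,
        "System": ss_c,
        "Season:System": ss_sc,
        "Genotype": ss_g,
        "Genotype:Season": ss_gs,
        "Genotype:System": ss_gc,
        "Genotype:Season:System": ss_gsc,
        "Error": ss_err,
    }

    ms = {k: (sss[k] / dfs[k] if dfs[k] > 0 else np.nan) for k in sss}
    ms_err = ms["Error"]
    ms_rep = ms["Rep"]
    rows = []
    env_sources = {"Season", "System", "Season:System"}
    for src in SOURCE_ORDER[:-1]:
        if src == "Error":
            f_val = p_val = np.nan
        elif src == "Rep":
            f_val = p_val = np.nan
        else:
            denom_ms, denom_df = (
                (ms_rep, dfs["Rep"])
                if (env_effects_against_rep and src in env_sources)
                else (ms_err, dfs["Error"])
            )
            if denom_ms and denom_ms > 0 and denom_df > 0:
                f_val = ms[src] / denom_ms
                p_val = float(stats.f.sf(f_val, dfs[src], denom_df))
            else:
                f_val = p_val = np.nan
        rows.append(
            {
                "source": src,
                "df": dfs[src],
                "SS": sss[src],
                "MS": ms[src],
                "F": f_val,
                "p": p_val,
                "pct_SS": 100.0 * sss[src] / ss_total if ss_total > 0 else 0.0,
            }
        )
    rows.append(
        {
            "source": "Total",
            "df": n - 1,
            "SS": ss_total,
            "MS": np.nan,
            "F": np.nan,
            "p": np.nan,
            "pct_SS": 100.0 if ss_total > 0 else 0.0,
        }
    )
    table_df = pd.DataFrame(rows)

    sd = float(np.std(y, ddof=1)) if n > 1 else 0.0
    cv = cv_percent(ss_err, dfs["Error"], grand) if grand > 0 else float("nan")
    return AnovaTable(
        trait=trait,
        rows=table_df,
        grand_mean=grand,
        min=float(y.min()),
        max=float(y.max()),
        sd=sd,
        cv_percent=cv,
    )


def pct_ss(anova: AnovaTable | pd.DataFrame, source: str) -> float:
    """Percent of the total SS attributable to one source, to 2 decimals."""
    rows = anova.rows if isinstance(anova, AnovaTable) else anova
    hit = rows[rows["source"] == source]
    if hit.empty:
        raise KeyError(f"unknown ANOVA source {source!r}")
    total = rows.loc[rows["source"] == "Total", "SS"]
    total_ss = float(total.iloc[0]) if not total.empty else float(rows["SS"].sum())
    return round(100.0 * float(hit["SS"].iloc[0]) / total_ss, 2)


def cv_percent(ss_error: float, df_error: int, grand_mean: float) -> float:
    """Coefficient of variation: 100·sqrt(SS_error/df_error)/grand mean."""
    if df_error <= 0:
        raise ValueError("df_error must be > 0")
    if grand_mean <= 0:
        raise ValueError("grand_mean must be > 0")
    return 100.0 * float(np.sqrt(ss_error / df_error)) / grand_mean
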