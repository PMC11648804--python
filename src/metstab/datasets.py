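"""Bundled reference tables from a published maize multi-environment trial.

The tables summarise a two-season evaluation of 24 maize hybrids (H1–H20
plus four commercial checks T1–T4) in West Java under three cropping
systems — sole maize, maize+soybean (IC1) and maize+sweet potato (IC2) —
with three replicates, for two traits: CWH (cob weight with husk,
biomass) and GY (grain yield), both in t·ha⁻¹.

They are summary statistics, not plot-level data: per-genotype trait
means and AMMI stability values with their published ranks, the combined
ANOVA sums of squares, trait descriptives, and the LER table per
intercrop × season.  The plot-level raw data live in a public repository
(Mendeley Data, accession vpschhv5kg/1) and are not bundled; pass its
CSV through :func:`metstab.core.read_trial_csv` to recompute everything
from scratch.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_stability_reference",
    "load_ler_reference",
    "load_anova_reference",
    "load_trait_summary_reference",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("metstab") / "reference" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_stability_reference(trait: str | None = None) -> pd.DataFrame:
    """Per-genotype mean, ASV and published ranks (rX, rASV, GSI, rGSI).

    Columns: trait, genotype, mean, asv, rank_mean, rank_asv, gsi,
    rank_gsi.  Filter by ``trait`` ("CWH" or "GY") if given.
    """
    df = _read("maize_stability.csv")
    if trait is not None:
        df = df[df["trait"] == trait].reset_index(drop=True)
        if df.empty:
            raise KeyError(f"unknown trait {trait!r}")
    return df


def load_ler_reference(trait: str | None = None) -> pd.DataFrame:
    """Published LER per genotype × intercrop system × season.

    Columns: trait, system (IC1 = maize+soybean, IC2 = maize+sweet
    potato), season (1, 2), genotype, LER.
    """
    df = _read("maize_ler.csv")
    if trait is not None:
        df = df[df["trait"] == trait].reset_index(drop=True)
        if df.empty:
            raise KeyError(f"unknown trait {trait!r}")
    return df


def load_anova_reference(trait: str) -> pd.DataFrame:
    """Combined-ANOVA df and SS columns for one trait (CWH or GY).

    Returns columns source, df, SS matching the layout produced by
    :func:`metstab.anova.combined_anova`.
    """
    df = _read("maize_anova_ss.csv")
    col = f"ss_{trait}"
    if col not in df.columns:
        raise KeyError(f"unknown trait {trait!r}")
    return df[["source", "df", col]].rename(columns={col: "SS"})


def load_trait_summary_reference() -> pd.DataFrame:
    """Grand mean, min, max, SD and CV% per trait."""
    return _read("maize_trait_summary.csv")
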