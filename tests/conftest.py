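"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from metstab import TrialTable, random_spec, simulate_trial


def make_balanced_table(
    g: int, s: int, c: int, r: int, rng: np.random.Generator, trait: str = "Y"
) -> TrialTable:
    """Random balanced table with arbitrary positive plot values."""
    rows = []
    for gi, si, ci, ri in itertools.product(range(g), range(s), range(c), range(r)):
        rows.append(
            (f"G{gi + 1}", f"S{si + 1}", f"C{ci + 1}", ri + 1, rng.uniform(1.0, 10.0))
        )
    df = pd.DataFrame(rows, columns=["genotype", "season", "system", "rep", trait])
    return TrialTable(df, traits=[trait])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def study_table() -> TrialTable:
    """Simulated trial with the study's exact shape: 24 × (2×3) × 3."""
    return simulate_trial(random_spec(seed=7))


@pytest.fixture(scope="session")
def noise_free_table() -> TrialTable:
    """Noise-free study-shaped trial (structural means observed exactly)."""
    spec = random_spec(seed=11, rep_effect_sd=0.0, noise_sd=0.0, grand_mean=50.0)
    return simulate_trial(spec)


# ----------------------------------------------------------------------
# Brute-force ANOVA oracle: per-plot enumeration of nested marginal means.
# Deliberately loop-based and independent of the vectorized implementation.


def brute_force_anova_ss(df: pd.DataFrame, trait: str) -> dict[str, float]:
    grand = df[trait].mean()

    def mean_of(row, factors):
        sub = df
        for f in factors:
            sub = sub[sub[f] == row[f]]
        return sub[trait].mean()

    acc = {k: 0.0 for k in (
        "Season", "System", "Season:System", "Genotype", "Genotype:Season",
        "Genotype:System", "Genotype:Season:System", "Rep", "Error", "Total",
    )}
    for _, row in df.iterrows():
        m_s = mean_of(row, ["season"])
        m_c = mean_of(row, ["system"])
        m_sc = mean_of(row, ["season", "system"])
        m_g = mean_of(row, ["genotype"])
        m_gs = mean_of(row, ["genotype", "season"])
        m_gc = mean_of(row, ["genotype", "system"])
        m_gsc = mean_of(row, ["genotype", "season", "system"])
        m_env_rep = mean_of(row, ["season", "system", "rep"])
        y = row[trait]
        acc["Season"] += (m_s - grand) ** 2
        acc["System"] += (m_c - grand) ** 2
        acc["Season:System"] += (m_sc - m_s - m_c + grand) ** 2
        acc["Genotype"] += (m_g - grand) ** 2
        acc["Genotype:Season"] += (m_gs - m_g - m_s + grand) ** 2
        acc["Genotype:System"] += (m_gc - m_g - m_c + grand) ** 2
        acc["Genotype:Season:System"] += (
            m_gsc - m_gs - m_gc - m_sc + m_g + m_s + m_c - grand
        ) ** 2
        acc["Rep"] += (m_env_rep - m_sc) ** 2
        acc["Error"] += (y - m_gsc - m_env_rep + m_sc) ** 2
        acc["Total"] += (y - grand) ** 2
    return acc


@pytest.fixture(scope="session")
def anova_oracle():
    return brute_force_anova_ss
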