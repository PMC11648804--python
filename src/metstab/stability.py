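"""Rank-based stability indexing: the Genotype Stability Index (GSI).

GSI combines performance and stability into one number per genotype:

    GSI_i = rASV_i + rX_i

where rX ranks the genotype trait means (rank 1 = highest mean) and rASV
ranks the AMMI stability values (rank 1 = lowest ASV, i.e. most stable).
Ties take competition ("min") ranks: tied values share the smallest rank
of their group and the next distinct value skips accordingly, so two
genotypes tied at the best GSI both get rank 1 and the next gets rank 3.
Lower GSI identifies genotypes that are simultaneously high-performing
and stable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ammi import AsvTable

__all__ = ["rank_values", "gsi", "StabilityTable"]

StabilityTable = pd.DataFrame  # columns: mean, rX, ASV, rASV, GSI, rGSI


def rank_values(values, direction: str = "descending") -> np.ndarray:
    """Competition (min) ranks of a value vector.

    ``direction="descending"`` gives rank 1 to the largest value (used for
    trait means); ``"ascending"`` gives rank 1 to the smallest (used for
    ASV and GSI).  NaN values are rejected.
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("cannot rank NaN values")
    if direction == "descending":
        v = -v
    elif direction != "ascending":
        raise ValueError("direction must be 'ascending' or 'descending'")
    return rankdata(v, method="min").astype(int)


def gsi(trait_means: pd.Series, asv_values: pd.Series | AsvTable) -> StabilityTable:
    """Genotype Stability Index table from trait means and ASVs.

    Parameters
    ----------
    trait_means
        Per-genotype trait means (t·ha⁻¹), indexed by genotype.
    asv_values
        Per-genotype ASV, indexed by genotype (or an
        :class:`~metstab.ammi.AsvTable`).

    Returns
    -------
    DataFrame indexed by genotype with columns ``mean, rX, ASV, rASV,
    GSI, rGSI``.

    Raises
    ------
    KeyError
        If the two inputs do not cover the same genotype set (the message
        lists the symmetric difference).
    """
    if isinstance(asv_values, AsvTable):
        asv_values = asv_values.asv
    left = set(trait_means.index)
    right = set(asv_values.index)
    if left != right:
        diff = sorted(left.symmetric_difference(right))
        raise KeyError(f"genotype sets differ between means and ASV: {diff}")
    genotypes = list(trait_means.index)
    means = trait_means.astype(float)
    asvs = asv_values.reindex(genotypes).astype(float)
    rx = rank_values(means.to_numpy(), "descending")
    rasv = rank_values(asvs.to_numpy(), "ascending")
    gsi_vals = rx + rasv
    rgsi = rank_values(gsi_vals, "ascending")
    out = pd.DataFrame(
        {
            "mean": means.to_numpy(),
            "rX": rx,
            "ASV": asvs.to_numpy(),
            "rASV": rasv,
            "GSI": gsi_vals,
            "rGSI": rgsi,
        },
        index=pd.Index(genotypes, name="genotype"),
    )
    return out
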