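"""AMMI decomposition and the AMMI Stability Value (ASV).

The additive-main-effects, multiplicative-interaction model fits genotype
and environment main effects by marginal means and decomposes the residual
genotype × environment interaction by SVD::

    Y_ij = mu + G_i + E_j + sum_k lambda_k alpha_ik gamma_jk + rho_ij

The double-centered matrix ``D_ij = Y_ij − Ȳ_i. − Ȳ_.j + Ȳ..`` holds the
interaction; its singular vectors are the interaction principal component
axes (IPCA).  A genotype's ASV is its weighted distance from the biplot
origin in the first two IPCA axes,

    ASV_i = sqrt( (w · IPCA1_i)² + IPCA2_i² ),   w = SS_IPCA1 / SS_IPCA2,

so genotypes with small ASV interact little with environments and are the
stable ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MeansMatrix

__all__ = [
    "BiplotDecomposition",
    "AsvTable",
    "ammi_decompose",
    "asv",
    "asv_from_scores",
]


class DecompositionError(ValueError):
    """The decomposition is degenerate for the requested operation."""


@dataclass
class BiplotDecomposition:
    """SVD of a centered genotype × environment table (AMMI or GGE).

    ``genotype_basis`` / ``environment_basis`` hold the orthonormal singular
    vectors; ``genotype_scores`` / ``environment_scores`` are the plotting
    coordinates after singular-value partitioning with exponent ``f``
    (genotype scores ∝ λ^f, environment scores ∝ λ^(1−f)).
    """

    model: str  # "AMMI" or "GGE"
    singular_values: np.ndarray
    genotype_basis: pd.DataFrame  # g × K, orthonormal columns
    environment_basis: pd.DataFrame  # e × K, orthonormal columns
    svp_exponent: float
    centering: str
    degenerate_spectrum: bool = False

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    @property
    def variance_proportion(self) -> np.ndarray:
        """Percent of the centered matrix SS carried by each component."""
        lam2 = self.singular_values**2
        total = lam2.sum()
        if total == 0:
            return np.zeros_like(lam2)
        return 100.0 * lam2 / total

    @property
    def genotype_scores(self) -> pd.DataFrame:
        scale = self.singular_values**self.svp_exponent
        return self.genotype_basis * scale

    @property
    def environment_scores(self) -> pd.DataFrame:
        scale = self.singular_values ** (1.0 - self.svp_exponent)
        return self.environment_basis * scale

    def scores_frame(self) -> pd.DataFrame:
        """Long-format coordinates: entity, label, PC1..PCk."""
        gs = self.genotype_scores.copy()
        gs.insert(0, "entity", "genotype")
        es = self.environment_scores.copy()
        es.insert(0, "entity", "environment")
        out = pd.concat([gs, es]).rename_axis("label").reset_index()
        return out[["entity", "label"] + [c for c in out.columns if c.startswith("PC")]]


@dataclass
class AsvTable:
    """Per-genotype IPCA1/IPCA2 scores and the AMMI Stability Value."""

    table: pd.DataFrame  # columns: IPCA1, IPCA2, ASV; index genotype
    weight: float  # SS_IPCA1 / SS_IPCA2

    @property
    def asv(self) -> pd.Series:
        return self.table["ASV"]


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve SVD sign indeterminacy: the largest-|u| genotype entry of each
    component is made positive (flipping u and v together)."""
    for k in range(u.shape[1]):
        idx = np.argmax(np.abs(u[:, k]))
        if u[idx, k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    return u, v


def _decompose(
    centered: np.ndarray,
    genotypes: list[str],
    env_labels: list[str],
    k: int | str,
    model: str,
    svp_exponent: float,
    centering: str,
) -> BiplotDecomposition:
    g, e = centered.shape
    kmax = min(g - 1, e - 1)
    if k == "max":
        k = kmax
    k = int(k)
    if k < 1 or k > kmax:
        raise ValueError(f"number of components must be in 1..{kmax}, got {k}")
    U, lam, Vt = np.linalg.svd(centered, full_matrices=False)
    U, V = _fix_signs(U[:, :k].copy(), Vt.T[:, :k].copy())
    lam = lam[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    degenerate = bool(
        k >= 2 and np.any(np.isclose(lam[:-1], lam[1:], rtol=1e-10, atol=1e-12))
    )
    return BiplotDecomposition(
        model=model,
        singular_values=lam,
        genotype_basis=pd.DataFrame(U, index=genotypes, columns=cols),
        environment_basis=pd.DataFrame(V, index=env_labels, columns=cols),
        svp_exponent=svp_exponent,
        centering=centering,
        degenerate_spectrum=degenerate,
    )


def ammi_decompose(
    means: MeansMatrix,
    k: int | str = "max",
    svp_exponent: float = 0.5,
) -> BiplotDecomposition:
    """AMMI decomposition of a genotype × environment means table.

    The table is double-centered (row means, column means and the grand
    mean removed) and the residual interaction decomposed by SVD.  The
    first two scaled score columns are the AMMI2 biplot coordinates;
    AMMI1 plots genotype/environment means against PC1.

    Requires at least 3 genotypes and 3 environments and a complete table.
    """
    Y = means.values.to_numpy(dtype=float)
    g, e = Y.shape
    if g < 3 or e < 3:
        raise ValueError(f"AMMI needs g >= 3 and e >= 3 (got {g} × {e})")
    if np.isnan(Y).any():
        raise ValueError("means table has missing cells")
    D = Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + Y.mean()
    return _decompose(
        D,
        means.genotypes,
        means.env_labels,
        k,
        model="AMMI",
        svp_exponent=svp_exponent,
        centering="double (genotype and environment means removed)",
    )


def ammi1_coordinates(means: MeansMatrix, dec: BiplotDecomposition) -> pd.DataFrame:
    """AMMI1 layout: entity mean on the abscissa, IPCA1 score on the ordinate."""
    gs = dec.genotype_scores["PC1"]
    es = dec.environment_scores["PC1"]
    rows = [
        {"entity": "genotype", "label": g, "mean": m, "IPCA1": gs[g]}
        for g, m in means.genotype_means().items()
    ] + [
        {"entity": "environment", "label": e, "mean": m, "IPCA1": es[e]}
        for e, m in means.environment_means().items()
    ]
    return pd.DataFrame(rows)


def asv_from_scores(ipca1, ipca2, weight: float):
    """ASV from explicit IPCA1/IPCA2 scores and a weight w = SS1/SS2."""
    ipca1 = np.asarray(ipca1, dtype=float)
    ipca2 = np.asarray(ipca2, dtype=float)
    if weight <= 0:
        raise ValueError("weight must be > 0")
    return np.sqrt((weight * ipca1) ** 2 + ipca2**2)


def asv(dec: BiplotDecomposition, score_scaling: str = "sqrt") -> AsvTable:
    """AMMI Stability Value for every genotype.

    ``score_scaling`` selects the IPCA score convention fed into the
    formula: ``"sqrt"`` (default) uses α·sqrt(λ) for both axes — the
    symmetric scaling dominant in the ASV literature — while ``"full"``
    uses α·λ.  Rankings are unaffected by simultaneous sign flips of any
    component.

    Raises
    ------
    DecompositionError
        If the decomposition has fewer than two components or λ₂ = 0
        (interaction rank < 2, the weight is undefined).
    """
    if dec.n_components < 2:
        raise DecompositionError("ASV needs at least two interaction components")
    lam1, lam2 = float(dec.singular_values[0]), float(dec.singular_values[1])
    if lam2 <= max(1e-12 * lam1, 0.0) or lam1 == 0.0:
        raise DecompositionError(
            "second singular value is zero: interaction rank < 2, ASV undefined"
        )
    if score_scaling == "sqrt":
        scale = np.sqrt([lam1, lam2])
    elif score_scaling == "full":
        scale = np.array([lam1, lam2])
    else:
        raise ValueError("score_scaling must be 'sqrt' or 'full'")
    scores = dec.genotype_basis[["PC1", "PC2"]].to_numpy() * scale
    w = lam1**2 / lam2**2  # SS_IPCA1 / SS_IPCA2
    vals = asv_from_scores(scores[:, 0], scores[:, 1], w)
    table = pd.DataFrame(
        {"IPCA1": scores[:, 0], "IPCA2": scores[:, 1], "ASV": vals},
        index=dec.genotype_basis.index,
    )
    table.index.name = "genotype"
    return AsvTable(table=table, weight=w)
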