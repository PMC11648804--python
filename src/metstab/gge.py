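"""GGE biplot analysis: decomposition and the three standard views.

The GGE model keeps genotype main effects together with the genotype ×
environment interaction: the means table is centered by environment
(column) means only, ``Z_ij = Y_ij − Ȳ_.j``, and Z is decomposed by SVD.
Scores are scaled by singular-value partitioning (SVP): genotype scores
∝ λ^f and environment scores ∝ λ^(1−f) with f = 1 (genotype-focused),
0 (environment-focused) or 0.5 (symmetric).

Three analytic views are computed from the first two components:

* **Discriminativeness vs representativeness** — each environment's vector
  length (discriminating power) and its angle to the average-environment
  axis, the direction of the mean environment vector (representativeness).
  Environments are typed: I (short vector — little discrimination), II
  (long vector, small angle — good test environments) and III (long
  vector, large angle — useful only for specific adaptation).
* **Mean vs stability** — each genotype's signed projection onto the
  average-environment axis (proportional to its overall mean performance)
  and its perpendicular distance from that axis (instability).
* **Which won where** — the convex hull of genotype scores partitioned
  into angular sectors by the rays where the winning (max-projection)
  genotype changes, i.e. the outward normals of the hull edges; every
  environment falls in exactly one sector and that sector's hull vertex is
  its winner.  Sectors holding one or more environments delimit
  mega-environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .ammi import BiplotDecomposition, _decompose
from .core import MeansMatrix

__all__ = [
    "GgeViews",
    "gge_decompose",
    "discriminativeness_representativeness",
    "mean_vs_stability",
    "which_won_where",
    "gge_views",
]

SVP_EXPONENTS = {"genotype": 1.0, "environment": 0.0, "symmetric": 0.5}


class DegenerateConfigurationError(ValueError):
    """The score configuration does not support the requested view."""


def gge_decompose(
    means: MeansMatrix,
    svp: str = "symmetric",
    k: int | str = "max",
    scale_environments: bool = False,
) -> BiplotDecomposition:
    """Environment-centered SVD of the means table (genotype + GEI retained).

    ``svp`` ∈ {"genotype", "environment", "symmetric"} chooses the
    singular-value partitioning. With ``scale_environments`` each column is
    additionally divided by its within-environment standard deviation
    before decomposition.
    """
    if svp not in SVP_EXPONENTS:
        raise ValueError(f"svp must be one of {sorted(SVP_EXPONENTS)}, got {svp!r}")
    Y = means.values.to_numpy(dtype=float)
    g, e = Y.shape
    if g < 3 or e < 3:
        raise ValueError(f"GGE needs g >= 3 and e >= 3 (got {g} × {e})")
    if np.isnan(Y).any():
        raise ValueError("means table has missing cells")
    Z = Y - Y.mean(axis=0, keepdims=True)
    centering = "environment (column means removed)"
    if scale_environments:
        sd = Y.std(axis=0, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("an environment has zero variance; cannot scale")
        Z = Z / sd
        centering += ", scaled by within-environment SD"
    return _decompose(
        Z,
        means.genotypes,
        means.env_labels,
        k,
        model="GGE",
        svp_exponent=SVP_EXPONENTS[svp],
        centering=centering,
    )


# ----------------------------------------------------------------------
# Shared geometry helpers


def _scores_2d(dec: BiplotDecomposition) -> tuple[pd.DataFrame, pd.DataFrame]:
    if dec.n_components < 2:
        raise ValueError("views need a decomposition with at least 2 components")
    return (
        dec.genotype_scores[["PC1", "PC2"]],
        dec.environment_scores[["PC1", "PC2"]],
    )


def average_environment_axis(dec: BiplotDecomposition) -> np.ndarray:
    """Unit vector along the mean of the environment score vectors."""
    _, env = _scores_2d(dec)
    mean_vec = env.to_numpy().mean(axis=0)
    norm = np.linalg.norm(mean_vec)
    if norm == 0:
        raise DegenerateConfigurationError(
            "average environment vector has zero length; AEA undefined"
        )
    return mean_vec / norm


# ----------------------------------------------------------------------
# View 1: discriminativeness vs representativeness


def discriminativeness_representativeness(
    dec: BiplotDecomposition,
    length_fraction: float = 0.5,
    angle_cutoff_deg: float = 45.0,
) -> pd.DataFrame:
    """Environment vector lengths, angles to the AEA, and type labels.

    Type I: length < ``length_fraction`` × max length (weakly
    discriminating). Type II: long vector with angle < ``angle_cutoff_deg``
    (discriminating and representative). Type III: long vector with a
    large angle (discriminating but unrepresentative).  The cutoffs are a
    reporting convention; raw lengths and angles are returned so other
    conventions can be applied.
    """
    _, env = _scores_2d(dec)
    aea = average_environment_axis(dec)
    V = env.to_numpy()
    lengths = np.linalg.norm(V, axis=1)
    max_len = lengths.max()
    with np.errstate(invalid="ignore"):
        cosang = np.where(
            lengths > 0, np.clip(V @ aea / np.where(lengths > 0, lengths, 1.0), -1, 1), 1.0
        )
    angles = np.degrees(np.arccos(cosang))
    types = np.where(
        lengths < length_fraction * max_len,
        "I",
        np.where(angles < angle_cutoff_deg, "II", "III"),
    )
    out = pd.DataFrame(
        {
            "PC1": V[:, 0],
            "PC2": V[:, 1],
            "vector_length": lengths,
            "angle_to_AEA_deg": angles,
            "env_type": types,
        },
        index=env.index,
    )
    out.index.name = "environment"
    return out


# ----------------------------------------------------------------------
# View 2: mean vs stability


def mean_vs_stability(dec: BiplotDecomposition) -> pd.DataFrame:
    """Genotype projections on the AEA and distances from it.

    ``mean_projection`` is the signed coordinate along the average-
    environment axis (larger ⇒ better average performance; > 0 ⇒ above
    the biplot average); ``stability_distance`` is the perpendicular
    distance from the axis (larger ⇒ less stable).
    """
    gen, _ = _scores_2d(dec)
    aea = average_environment_axis(dec)
    perp = np.array([-aea[1], aea[0]])
    G = gen.to_numpy()
    proj = G @ aea
    dist = np.abs(G @ perp)
    out = pd.DataFrame(
        {
            "PC1": G[:, 0],
            "PC2": G[:, 1],
            "mean_projection": proj,
            "stability_distance": dist,
            "above_average": proj > 0,
        },
        index=gen.index,
    )
    out.index.name = "genotype"
    return out


# ----------------------------------------------------------------------
# View 3: which won where


def _ccw_hull(points: np.ndarray) -> list[int]:
    """Indices of convex-hull vertices in counter-clockwise order."""
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise DegenerateConfigurationError(
            "genotype scores are collinear; convex hull (and the "
            "which-won-where partition) is degenerate"
        ) from exc
    return list(hull.vertices)  # scipy returns CCW order in 2-D


def which_won_where(dec: BiplotDecomposition) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sector partition of the biplot and the winning genotype per sector.

    Returns ``(sectors, assignments)``:

    * ``sectors`` — one row per convex-hull vertex genotype with the
      angular interval ``[start_angle_deg, end_angle_deg)`` it wins
      (counter-clockwise, degrees in [0, 360)), the member environments
      and a mega-environment flag (≥ 1 member environment).
    * ``assignments`` — one row per environment: its angle, its sector's
      vertex (winning) genotype.

    The sector boundaries are the directions perpendicular to the hull
    edges — exactly where the maximal-projection genotype changes — so
    within each sector the vertex genotype has the greatest projection
    onto every environment vector in it.  An environment lying exactly on
    a boundary ray is assigned to the counter-clockwise sector.
    """
    gen, env = _scores_2d(dec)
    G = gen.to_numpy()
    V = env.to_numpy()
    verts = _ccw_hull(G)
    m = len(verts)
    names = list(gen.index)

    # outward normal of each CCW edge = boundary ray where the winner
    # switches from the edge's first vertex to its second
    boundary = np.empty(m)
    for t in range(m):
        a = G[verts[t]]
        b = G[verts[(t + 1) % m]]
        edge = b - a
        normal = np.array([edge[1], -edge[0]])  # CCW polygon -> outward
        boundary[t] = np.degrees(np.arctan2(normal[1], normal[0])) % 360.0

    # sector of vertex t spans from the boundary before it to the one after
    sectors_rows = []
    intervals = []
    for t in range(m):
        start = boundary[(t - 1) % m]
        end = boundary[t]
        intervals.append((start, end))
        sectors_rows.append(
            {
                "vertex_genotype": names[verts[t]],
                "start_angle_deg": start,
                "end_angle_deg": end,
            }
        )

    def in_interval(angle: float, start: float, end: float) -> bool:
        # CCW half-open interval [start, end) on the circle
        a = (angle - start) % 360.0
        width = (end - start) % 360.0
        if width == 0:  # single sector covering the full circle
            return True
        return a < width

    env_angles = np.degrees(np.arctan2(V[:, 1], V[:, 0])) % 360.0
    members: dict[int, list[str]] = {t: [] for t in range(m)}
    assign_rows = []
    for label, ang, vec in zip(env.index, env_angles, V):
        winner = None
        for t, (start, end) in enumerate(intervals):
            if in_interval(ang, start, end):
                winner = t
                break
        if winner is None:  # numerically on a boundary: take the CCW side
            winner = int(np.argmin((boundary - ang) % 360.0))
            winner = (winner + 1) % m
        members[winner].append(str(label))
        assign_rows.append(
            {
                "environment": str(label),
                "angle_deg": ang,
                "winner": names[verts[winner]],
            }
        )

    for t, row in enumerate(sectors_rows):
        row["environments"] = ";".join(members[t])
        row["n_environments"] = len(members[t])
        row["mega_environment"] = len(members[t]) >= 1
    sectors = pd.DataFrame(sectors_rows)
    assignments = pd.DataFrame(assign_rows)
    return sectors, assignments


@dataclass
class GgeViews:
    """Bundle of the decomposition and the three computed views."""

    decomposition: BiplotDecomposition
    aea_direction: np.ndarray
    env_metrics: pd.DataFrame
    genotype_metrics: pd.DataFrame
    sectors: pd.DataFrame
    assignments: pd.DataFrame

    @property
    def mega_environments(self) -> pd.DataFrame:
        return self.sectors[self.sectors["n_environments"] >= 1].reset_index(drop=True)


def gge_views(means: MeansMatrix, svp: str = "symmetric") -> GgeViews:
    """Compute all three GGE views from one means table.

    Each view uses the SVP convention standard for it (environment-focused
    for discriminativeness, genotype-focused for mean-vs-stability, the
    caller's ``svp`` — symmetric by default — for which-won-where).
    """
    dec = gge_decompose(means, svp=svp, k="max")
    dec_env = gge_decompose(means, svp="environment", k="max")
    dec_gen = gge_decompose(means, svp="genotype", k="max")
    sectors, assignments = which_won_where(dec)
    return GgeViews(
        decomposition=dec,
        aea_direction=average_environment_axis(dec),
        env_metrics=discriminativeness_representativeness(dec_env),
        genotype_metrics=mean_vs_stability(dec_gen),
        sectors=sectors,
        assignments=assignments,
    )
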