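"""Synthetic multi-environment trial generator.

Plot values are drawn from the additive-main-effects, multiplicative-
interaction structure the downstream analyses assume::

    Y_ijk = mu + G_i + E_j + sum_t lambda_t * alpha_it * gamma_jt
            + r_k(j) + eps_ijk

with genotype effects ``G`` and environment effects ``E`` summing to zero,
a rank-``K`` genotype-by-environment interaction given by singular values
``lambda`` and orthonormal score matrices ``alpha`` (genotypes) and
``gamma`` (environments), Gaussian replication-within-environment effects
``r`` and i.i.d. Gaussian plot noise ``eps``.

The default dimensions mirror a two-season, three-cropping-system maize
hybrid trial: 24 genotypes × 6 environments × 3 replicates (432 plots).
Default effect scales are calibrated to the variance partition such trials
typically show (cropping system dominating the environmental variance,
plot CV near 20%); see the package methods note for the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import TrialTable

__all__ = ["SimulationSpec", "SpecError", "random_spec", "simulate_trial"]

# Study-shaped defaults used by random_spec / the CLI `simulate` subcommand.
DEFAULT_GRAND_MEAN = 7.43  # t/ha, biomass-scale
DEFAULT_GENOTYPE_SD = 0.75
DEFAULT_ENVIRONMENT_SD = 3.1
DEFAULT_SINGULAR_VALUES = (10.0, 6.0)
DEFAULT_REP_SD = 0.15
DEFAULT_NOISE_SD = 1.48


class SpecError(ValueError):
    """A SimulationSpec invariant is violated; the message names the field."""


@dataclass
class SimulationSpec:
    """Ground-truth parameters for one simulated trial.

    Invariants (checked by :meth:`validate`): genotype and environment
    effects sum to zero; score matrices have orthonormal columns; singular
    values are non-negative and non-increasing; K ≤ min(g−1, e−1).
    """

    n_genotypes: int
    n_seasons: int
    n_systems: int
    n_reps: int
    grand_mean: float
    genotype_effects: np.ndarray
    environment_effects: np.ndarray
    gei_singular_values: np.ndarray
    gei_genotype_scores: np.ndarray  # g × K, orthonormal columns
    gei_environment_scores: np.ndarray  # e × K, orthonormal columns
    rep_effect_sd: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    trait_name: str = "Y"
    genotype_names: list[str] = field(default_factory=list)

    @property
    def n_environments(self) -> int:
        return self.n_seasons * self.n_systems

    @property
    def gei_rank(self) -> int:
        return len(self.gei_singular_values)

    def validate(self) -> None:
        g, e, K = self.n_genotypes, self.n_environments, self.gei_rank
        if g < 1 or self.n_seasons < 1 or self.n_systems < 1 or self.n_reps < 1:
            raise SpecError("n_genotypes/n_seasons/n_systems/n_reps must be >= 1")
        if K > min(g - 1, e - 1):
            raise SpecError(
                f"gei_singular_values: rank K={K} exceeds min(g-1, e-1)="
                f"{min(g - 1, e - 1)}"
            )
        G = np.asarray(self.genotype_effects, dtype=float)
        E = np.asarray(self.environment_effects, dtype=float)
        if G.shape != (g,):
            raise SpecError(f"genotype_effects: expected shape ({g},), got {G.shape}")
        if E.shape != (e,):
            raise SpecError(f"environment_effects: expected shape ({e},), got {E.shape}")
        if abs(G.sum()) > 1e-8 * max(1.0, np.abs(G).max(initial=1.0)):
            raise SpecError("genotype_effects: must sum to zero")
        if abs(E.sum()) > 1e-8 * max(1.0, np.abs(E).max(initial=1.0)):
            raise SpecError("environment_effects: must sum to zero")
        lam = np.asarray(self.gei_singular_values, dtype=float)
        if (lam < 0).any():
            raise SpecError("gei_singular_values: must be >= 0")
        if (np.diff(lam) > 1e-12).any():
            raise SpecError("gei_singular_values: must be non-increasing")
        if K:
            A = np.asarray(self.gei_genotype_scores, dtype=float)
            C = np.asarray(self.gei_environment_scores, dtype=float)
            if A.shape != (g, K):
                raise SpecError(
                    f"gei_genotype_scores: expected shape ({g}, {K}), got {A.shape}"
                )
            if C.shape != (e, K):
                raise SpecError(
                    f"gei_environment_scores: expected shape ({e}, {K}), got {C.shape}"
                )
            if not np.allclose(A.T @ A, np.eye(K), atol=1e-8):
                raise SpecError("gei_genotype_scores: columns must be orthonormal")
            if not np.allclose(C.T @ C, np.eye(K), atol=1e-8):
                raise SpecError("gei_environment_scores: columns must be orthonormal")
        if self.rep_effect_sd < 0:
            raise SpecError("rep_effect_sd: must be >= 0")
        if self.noise_sd < 0:
            raise SpecError("noise_sd: must be >= 0")

    # -- ground-truth structure -----------------------------------------
    def gei_matrix(self) -> np.ndarray:
        """The planted g × e interaction matrix sum_t lambda_t alpha_t gamma_t'."""
        if not self.gei_rank:
            return np.zeros((self.n_genotypes, self.n_environments))
        A = np.asarray(self.gei_genotype_scores, dtype=float)
        C = np.asarray(self.gei_environment_scores, dtype=float)
        lam = np.asarray(self.gei_singular_values, dtype=float)
        return (A * lam) @ C.T

    def structural_means(self) -> np.ndarray:
        """Noise-free g × e cell means: mu + G_i + E_j + GEI_ij."""
        G = np.asarray(self.genotype_effects, dtype=float)
        E = np.asarray(self.environment_effects, dtype=float)
        return self.grand_mean + G[:, None] + E[None, :] + self.gei_matrix()

    # -- flat serialisation ---------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        d = yaml.safe_load(Path(path).read_text())
        for k in (
            "genotype_effects",
            "environment_effects",
            "gei_singular_values",
            "gei_genotype_scores",
            "gei_environment_scores",
        ):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def _centered_orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Draw an n × k matrix with zero-sum, orthonormal columns.

    Columns are centered before QR so the planted interaction matrix is
    already double-centered — AMMI then recovers the planted singular
    values exactly in the noise-free limit.
    """
    if k == 0:
        return np.zeros((n, 0))
    X = rng.standard_normal((n, k))
    X -= X.mean(axis=0)
    Q, R = np.linalg.qr(X)
    # deterministic sign: make diag(R) positive
    Q = Q * np.sign(np.diag(R))
    return Q


def random_spec(
    n_genotypes: int = 24,
    n_seasons: int = 2,
    n_systems: int = 3,
    n_reps: int = 3,
    gei_rank: int = 2,
    seed: int = 0,
    grand_mean: float = DEFAULT_GRAND_MEAN,
    genotype_sd: float = DEFAULT_GENOTYPE_SD,
    environment_sd: float = DEFAULT_ENVIRONMENT_SD,
    gei_singular_values: tuple[float, ...] | None = None,
    rep_effect_sd: float = DEFAULT_REP_SD,
    noise_sd: float = DEFAULT_NOISE_SD,
    trait_name: str = "Y",
) -> SimulationSpec:
    """Draw a valid :class:`SimulationSpec` reproducibly from a seed.

    Effects are drawn Gaussian then centered; score matrices are drawn
    Gaussian then centered and orthonormalized (QR with a fixed sign
    convention), so every spec invariant holds by construction.
    """
    e = n_seasons * n_systems
    if gei_rank > min(n_genotypes - 1, e - 1):
        raise SpecError(
            f"gei_rank={gei_rank} exceeds min(g-1, e-1)={min(n_genotypes - 1, e - 1)}"
        )
    rng = np.random.default_rng(seed)
    G = rng.normal(0.0, genotype_sd, n_genotypes)
    G -= G.mean()
    E = rng.normal(0.0, environment_sd, e)
    E -= E.mean()
    if gei_singular_values is None:
        base = np.asarray(DEFAULT_SINGULAR_VALUES, dtype=float)
        lam = base[:gei_rank] if gei_rank <= len(base) else np.sort(
            rng.uniform(1.0, base[0], gei_rank)
        )[::-1]
        lam = np.sort(np.asarray(lam, dtype=float))[::-1]
    else:
        lam = np.asarray(gei_singular_values, dtype=float)
        if len(lam) != gei_rank:
            raise SpecError("gei_singular_values: length must equal gei_rank")
    A = _centered_orthonormal(rng, n_genotypes, gei_rank)
    C = _centered_orthonormal(rng, e, gei_rank)
    spec = SimulationSpec(
        n_genotypes=n_genotypes,
        n_seasons=n_seasons,
        n_systems=n_systems,
        n_reps=n_reps,
        grand_mean=grand_mean,
        genotype_effects=G,
        environment_effects=E,
        gei_singular_values=lam,
        gei_genotype_scores=A,
        gei_environment_scores=C,
        rep_effect_sd=rep_effect_sd,
        noise_sd=noise_sd,
        seed=seed,
        trait_name=trait_name,
        genotype_names=[f"H{i + 1}" for i in range(n_genotypes)],
    )
    spec.validate()
    return spec


def simulate_trial(spec: SimulationSpec) -> TrialTable:
    """Generate a balanced plot-level trial table from a spec.

    Identical specs (including seed) produce identical tables. Seasons are
    labelled S1, S2, ...; cropping systems "sole", "soybean", "sweetpotato"
    for the first three and "sysN" beyond; genotype names come from the
    spec (H1, H2, ... by default).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g, e, r = spec.n_genotypes, spec.n_environments, spec.n_reps
    genotypes = spec.genotype_names or [f"H{i + 1}" for i in range(g)]
    if len(genotypes) != g:
        raise SpecError("genotype_names: length must equal n_genotypes")
    seasons = [f"S{i + 1}" for i in range(spec.n_seasons)]
    system_pool = ["sole", "soybean", "sweetpotato"]
    systems = [
        system_pool[i] if i < len(system_pool) else f"sys{i + 1}"
        for i in range(spec.n_systems)
    ]
    # environment order: sorted by season then system, matching TrialTable
    envs = [(s, c) for s in seasons for c in sorted(systems)]

    structural = spec.structural_means()  # g × e
    rep_effects = rng.normal(0.0, spec.rep_effect_sd, (e, r)) if spec.rep_effect_sd else np.zeros((e, r))
    noise = rng.normal(0.0, spec.noise_sd, (g, e, r)) if spec.noise_sd else np.zeros((g, e, r))

    rows = []
    for i, gen in enumerate(genotypes):
        for j, (s, c) in enumerate(envs):
            for k in range(r):
                y = structural[i, j] + rep_effects[j, k] + noise[i, j, k]
                rows.append((gen, s, c, k + 1, y))
    df = pd.DataFrame(
        rows, columns=["genotype", "season", "system", "rep", spec.trait_name]
    )
    # yields are physical quantities; the calibrated defaults keep negative
    # draws vanishingly rare, but clip at zero to honour the data model
    df[spec.trait_name] = df[spec.trait_name].clip(lower=0.0)
    return TrialTable(df, traits=[spec.trait_name])
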