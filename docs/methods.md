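# Methods

This note documents the statistical models metstab implements, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Data model

A trial is a balanced factorial of g genotypes × s seasons × c cropping
systems × r replicates, one plot per record, traits in t·ha⁻¹. An
*environment* is one season × system combination; labels C1, C2, … are
assigned by sorting on (season, system), which for systems named
`sole < soybean < sweetpotato` reproduces the conventional ordering
(season 1 sole, +soybean, +sweet potato; then season 2 likewise).
Replication is treated as nested in environment: the replication term of
the combined ANOVA has s·c·(r−1) degrees of freedom (12 for the default
2×3×3 shape), which is the only layout consistent with a single
pooled-error stratum of df 276 in the 24-hybrid design. A separate
block-within-replicate term is not estimable from that layout and is
folded into replication/error.

Missing genotype × environment cells are an error by default;
`cell_means(..., impute_missing=True)` fills a cell with the additive
expectation (genotype mean + environment mean − grand mean). Silent
imputation is deliberately avoided.

## Combined ANOVA

All sums of squares are classical balanced-design marginal-mean
quantities, computed by the cell-SS recursion
`SS(A×B) = C(A,B) − SS(A) − SS(B)` with
`C(F) = Σ_cells n_cell (ȳ_cell − ȳ)²`; the error SS is the total minus
all listed effects. On balanced data this is exactly sequential (Type I)
OLS ANOVA, and the test suite cross-checks both against a per-plot
enumeration oracle and against statsmodels `anova_lm`.

F ratios use the pooled error MS for every tested effect by default;
`env_effects_against_rep=True` switches S, C and S×C to the
replication-within-environment MS (the stricter convention when
environments are treated as a mixed stratum). Either way replication and
error themselves carry no F. The trial CV% is
`100·√(MS_error)/grand mean`; SD is the plot-level standard deviation
(descriptive, ddof = 1).

## AMMI and the ASV

AMMI double-centers the g × e cell-mean table
(`D = Y − rowmean − colmean + grandmean`) and takes its SVD. Up to
K = min(g−1, e−1) components are retained; `Σ λ_k²` equals the
interaction SS exactly and reconstruction at full rank is an identity
(both are tested at 1e-10).

Conventions:

* **Sign** — SVD columns are flipped so the genotype entry of largest
  magnitude is positive in each component; environment vectors flip with
  them. This is pure reproducibility; no reported quantity depends on it.
* **IPCA scores for the ASV** — symmetric scaling `α_ik √λ_k` by default
  (the dominant convention in the ASV literature), with `α_ik λ_k`
  available via `score_scaling="full"`. The weight is always
  `w = λ₁²/λ₂² = SS_IPCA1/SS_IPCA2`.
* **Degenerate spectra** — near-equal singular values are returned in
  SVD order with `degenerate_spectrum=True`; no rotation is attempted.
  If λ₂ is numerically zero (interaction rank < 2) the ASV is undefined
  and an error is raised rather than a 0/0.

Both AMMI1 (mean vs IPCA1) and AMMI2 (IPCA1 vs IPCA2) coordinate layouts
are exported; the package does not privilege one.

## GGE biplots

GGE centers by environment only (`Z = Y − colmean`), retaining genotype
main effect plus interaction, and decomposes Z by SVD. Scores are scaled
by singular-value partitioning: genotype scores ∝ λ^f, environment
scores ∝ λ^(1−f), with f = 1 (genotype-focused), 0
(environment-focused), 0.5 (symmetric). No within-environment scaling is
applied by default (`scale_environments=True` adds SD-scaling); the
unscaled, environment-centered variant is the most common default and
keeps the biplot in yield units.

View conventions, chosen where the field admits more than one:

* Each view uses the SVP standard for it — environment-focused for
  discriminativeness vs representativeness, genotype-focused for mean vs
  stability, symmetric (configurable) for which-won-where.
* The average-environment axis (AEA) is the normalized mean of the
  environment score vectors. Environment typing is a reporting
  convention: type I if vector length < 0.5 × the longest; otherwise
  type II when the AEA angle < 45° and type III when ≥ 45°. Raw lengths
  and angles are always reported so users can apply other cutoffs.
* Which-won-where partitions the plane by the directions perpendicular
  to the convex-hull edges of the genotype scores — precisely the
  directions where the maximal-projection genotype changes. Implemented
  via outward edge normals, this is identical to the textbook
  "rays perpendicular to hull edges" construction when the origin lies
  inside the hull, and remains the exact argmax-projection partition
  when it does not, so every sector contains exactly one hull vertex and
  the vertex genotype provably wins every environment in its sector
  (tested against an exhaustive projection oracle). An environment
  falling exactly on a boundary ray joins the counter-clockwise sector.
  Sectors holding at least one environment are flagged as
  mega-environments.

## GSI and LER

Ranks are competition ("min") ranks throughout: tied values share the
minimum rank of the tie group and the next distinct value skips. This is
the only tie rule consistent with two genotypes sharing GSI rank 1 while
the next receives rank 3, as the bundled reference table shows. Higher
trait mean ⇒ rank 1; lower ASV ⇒ rank 1; GSI = rASV + rX; rGSI ranks GSI
ascending.

LER sums intercrop/sole yield ratios over component crops; it is
scale-invariant and strictly increasing in each intercrop yield.
"Favorable" means LER strictly greater than 1 (LER = 1 is the neutral
substitutive case). Because a maize trial records only the maize trait,
`ler_from_trial` computes the maize partial ratio (intercrop mean ÷
same-season sole mean per genotype) and accepts companion-crop
components from a separate CSV; `maize_only=True` reports the partial
LER alone. Whether a published total LER includes companion ratios is
not always recoverable from the totals, so both modes are first-class.

## Synthetic-data generator

`simulate_trial` draws
`Y_ijk = μ + G_i + E_j + Σ_t λ_t α_it γ_jt + r_k(j) + ε_ijk` with
centered effects, orthonormal score matrices, and Gaussian replication
and plot noise. Score columns are centered before QR-orthonormalization,
so the planted interaction matrix is already double-centered and AMMI
recovers the planted singular values exactly in the noise-free limit —
this is what makes the 1e-8 recovery tests meaningful rather than
approximate.

Defaults mirror the reference trial's dimensionality (24 genotypes,
2 seasons × 3 systems, 3 replicates) and its variance magnitudes, read
off the published mean squares by standard variance-component
arithmetic: grand mean 7.43 t·ha⁻¹, plot noise SD 1.48 (CV ≈ 20%),
genotype effect SD 0.75, environment effect SD 3.1 (environments — in
the real trial, chiefly the cropping system — dominate), replication SD
0.15 (the replication MS sits at the error MS), and a rank-2 interaction
with singular values (10, 6) matching the interaction SS share.
Environment effects are drawn at the environment level, so the S/C/S×C
split of the environmental SS varies by seed rather than being pinned to
the real trial's extreme system-dominance; tests that depend on the
split therefore assert structure (df, additivity, oracles), not the
share itself. Yields are clipped at zero to respect the data model; the
calibrated defaults make clipping vanishingly rare, and tests needing
exactness raise the grand mean instead of disabling the clip.

The generator emulates the *statistical* structure the analyses assume —
balance, Gaussian errors, low-rank interaction. It does not emulate
spatial field trend, heteroscedastic or skewed errors, genetic
relatedness among hybrids, or missing plots; passing tests therefore
demonstrate correctness of the estimators under their own model, not
robustness to field-data pathologies.

## Problem sizes and tolerances

The test suite runs the full study-shaped design (432 plots) for
integration checks and smaller factorials (≤ 200 plots) against the
enumeration oracle; recovery tests use 50 random noise-free specs at
1e-8 relative tolerance, and the which-won-where oracle runs 100 random
configurations. Exact identities (SS additivity, reconstruction, SS
conservation) are asserted at 1e-8–1e-10 relative; Monte-Carlo checks
(null F means) use 150 replicates with a ±0.2 band around the exact
F-distribution mean.

## Known limitations

* Balanced designs only; unbalanced data must be imputed to balance
  (additive cell means) or analysed elsewhere — there is no REML/mixed
  model and no Type II/III SS.
* No significance tests on AMMI components (Gollob/FR) and no bootstrap
  confidence regions on biplots.
* Figure rendering is out of scope: the package exports coordinates and
  metrics, not images.
* The GSI weights performance and stability ranks equally; no weighted
  variant is provided.
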