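# metstab

Stability analysis for multi-environment crop trials (METs): which
genotypes yield well *and* consistently when the same set of hybrids is
grown across several environments — here, season × cropping-system
combinations such as sole maize versus maize intercropped with soybean or
sweet potato.

The package is aimed at plant breeders and agronomists analysing
plot-level yield data (t·ha⁻¹) from balanced factorial trials. It
implements the full standard tool chain:

* **Combined ANOVA** — partition of plot variation into replication
  (nested in environment), season S, cropping system C, S×C, genotype G,
  G×S, G×C, G×S×C and error, with %SS, F tests and the trial CV%.
* **AMMI** — the additive-main-effects, multiplicative-interaction model
  `Y_ij = μ + G_i + E_j + Σ_k λ_k α_ik γ_jk + ρ_ij`: an SVD of the
  double-centered genotype × environment means, giving interaction
  principal component (IPCA) scores and biplot coordinates.
* **ASV** — the AMMI stability value
  `ASV_i = √((w·IPCA1_i)² + IPCA2_i²)` with `w = SS_IPCA1/SS_IPCA2`;
  small ASV = small interaction = a stable genotype.
* **GGE biplots** — SVD of the environment-centered means (genotype main
  effect retained), with the three analytic views: discriminativeness vs
  representativeness, mean vs stability (projection on the
  average-environment axis), and which-won-where (convex-hull sectors and
  mega-environments).
* **GSI** — the genotype stability index `GSI = rASV + rX`, the sum of a
  genotype's stability rank and its performance rank (competition/min
  ranks; lower is better).
* **LER** — the land equivalent ratio `LER = Σ_i IC_i / C_i` over the
  component crops of an intercrop; LER > 1 marks a land-use advantage.
* **Synthetic trials** — a generator that plants exactly the structure
  these methods estimate (additive effects + low-rank interaction +
  replication effects + noise), so every stage is testable against known
  ground truth.

## Worked example

Rank 24 maize hybrids for biomass (CWH, cob weight with husk) using the
bundled reference tables from a two-season West Java hybrid trial:

```python
from metstab import gsi
from metstab.datasets import load_stability_reference

ref = load_stability_reference("CWH").set_index("genotype")
print(gsi(ref["mean"], ref["asv"]).sort_values(["rGSI", "GSI"]).head(6))
```

```
              mean  rX       ASV  rASV  GSI  rGSI
genotype
H1        8.756975   3  0.227756     4    7     1
H4        7.900556   5  0.165171     2    7     1
H16       7.763774   7  0.383488     7   14     3
H18       7.390317  11  0.343528     6   17     4
H6        7.244609  15  0.181854     3   18     5
T2        7.517938   9  0.535984    12   21     6
```

H1 is only the 3rd-highest yielder but the 4th most stable, so its GSI of
7 ties H4 for the best combined score — exactly the trade-off the index
is built to expose: H12, the top yielder, has the *worst* ASV rank (24)
and drops to GSI rank 11.

The same analyses run from the shell on any long-format trial CSV
(columns: genotype, season, system, rep, one column per trait). With a
synthetic trial:

```sh
$ metstab --quiet simulate --seed 1 --out trial.csv
wrote 432 plots to trial.csv
$ metstab --quiet anova --trait GY --input trial.csv --out anova.csv
GY: grand mean 7.366 t/ha, CV 19.00%
$ metstab --quiet gge --trait GY --input trial.csv --out-dir gge_out
PC1 52.16%, PC2 25.15% of G+GE variation
```

The ANOVA table (`anova.csv`) for this 24 × (2×3) × 3 design carries the
classic df column 12, 1, 2, 2, 23, 23, 46, 46, 276 (total 431). A single
YAML config can drive the whole pipeline (`metstab run --config
config.yml`), writing ANOVA, AMMI scores, ASV, GGE views, GSI and LER
tables plus a ranking summary in one pass.

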