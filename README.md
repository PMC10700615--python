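# marshcascade

Analysis pipeline for trophic-cascade restoration experiments in coastal
wetlands. The scientific setting: migratory shorebirds prey on burrowing,
plant-grazing crabs; losing the birds releases the crabs, which graze down
newly planted marsh vegetation and churn the sediment, degrading a broad
set of wetland ecosystem functions. The package analyses a 4-treatment ×
8-plot field design (natural-recovery control, planting control,
planting + shorebird exclusion, planting + high-predation simulation) and
ships a seeded synthetic-data generator that emulates that design, so the
whole pipeline runs and is testable without any field-data download.

It is intended for restoration ecologists and biostatisticians who want
the full computation chain — raw plot measurements → ecosystem functions →
multifunctionality metrics → treatment inference → trophic effect sizes —
as tested, reusable library code with stable delimited-text schemas.

## What it computes

**Twelve ecosystem functions per plot**, from field measurements:
primary production (allometric stem biomass, *M* = 0.0004·*H*^1.72, plus
cored belowground biomass), macrofaunal secondary production, microbial
production (qPCR gene copies), wave dissipation (gypsum-block dissolution),
marsh infiltration, sediment accretion, soil respiration, net N
mineralization, litter decomposition (*L_t* = *L*₀e^(−*kt*)), sediment
carbon burial (accretion × SOC% × bulk density), N accumulation, and soil
heavy-metal reduction (Nemerow multifactor index). Cost-scale functions are
reoriented with the benefit transform −*f*ᵢ + max(*f*ᵢ), where max(*f*ᵢ) is
the mean of the three largest values, so larger always means more benefit.

**Multifunctionality.** Each function is standardized columnwise (percent
of maximum, or 0–1), then summarized per plot by the unweighted averaged
index *A* and by Hill-number metrics: with *p*ᵢ = *F*ᵢ/Σ*F*ᵢ,

    N^q = (Σᵢ pᵢ^q)^(1/(1−q))   (q ≥ 0, q ≠ 1),
    N^1 = exp(−Σᵢ pᵢ ln pᵢ),

the effective number of functions, and effective multifunctionality
^q*M*_ef = *N*^q·*A*. *N*⁰ counts the functions provided; larger *q*
upweights the best-performing functions.

**Trophic effect sizes.** Log response ratios LRR = ln *X*_P − ln *X*_E
with delta-method variance Var = *S*_E²/(*N*_E*X*_E²) + *S*_P²/(*N*_P*X*_P²),
DerSimonian–Laird random-effects pooling, per-month shorebird-exclusion
effects on crab burrow counts (x + 1 shifted), inverse-variance
meta-regression of those effects on monthly bird abundance, tethering
predation intensity (*M*_p·100/*M*) with a one-sample Wilcoxon test, and
the historical back-projection of crab density to the pre-collapse
shorebird population,

    D_hist = D_C + [(D_C − D_E)/(p·N_now)]·(N_hist − N_now).

**Treatment inference.** One-way ANOVA with Tukey HSD and compact letter
displays, pairwise rank-sum tests with Bonferroni adjustment, pairwise
proportion tests, first-week plant-loss slopes, linear-vs-quadratic
selection by AICc, and Spearman correlation matrices.

## Worked example

```python
import marshcascade as mc
from marshcascade.io import percent_changes

ds = mc.generate_experiment(mc.ExperimentConfig(seed=42))
matrix = mc.build_function_matrix(ds.raw)        # 32 plots x 12 functions
table = mc.multifunctionality_table(matrix)      # avg index, N^q, M_ef

print(percent_changes(table["avg_index"], table["treatment"]))
```

prints (seed 42):

```
{'natural_recovery_control': 6.710173281187673,
 'planting_exclusion': 1.10091191656504,
 'planting_predation_sim': 65.59692144463146}
```

i.e. relative to the planting-control arm of this simulated experiment,
simulating historically high predation (crab removal) raised the averaged
multifunctionality index by ~66%, while the exclusion and natural-recovery
arms sit near planting alone on the averaged index: under the default
generating effects shorebird exclusion depresses four
sediment/biogeochemical functions but boosts soil respiration, so its
per-function contrasts (in `matrix`) carry most of the signal. Monthly
exclusion effects on crabs:

```python
effs = mc.exclusion_effect_on_crabs(ds.burrows)   # one LRR per month
pooled = mc.pooled_random_effects(effs)
print(round(pooled.lrr, 3), pooled.significant)   # 1.283 True
```

a pooled log response ratio of ~1.3: shorebird exclusion increased crab
abundance about 3.6-fold on average, strongest in migration months.

The same stages are scriptable from the shell:

```sh
marshcascade all --seed 42 --out run42      # simulate + full pipeline
marshcascade simulate --seed 42 --out data  # write input tables only
marshcascade functions data/plots.csv       # stage by stage
```

`marshcascade all` writes the function matrix, multifunctionality and
comparison tables, monthly effect sizes, and a machine-readable
`summary.json` (treatment means, percent changes vs planting control,
ANOVA results, letters). Field datasets in the same delimited-text schemas
(see `marshcascade.io`) are drop-in replacements for the simulated tables
via `--input-dir`.

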