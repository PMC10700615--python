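# Methods

This note documents the models, estimators, numerical conventions, and
design choices behind `marshcascade`, and what the synthetic-data tests do
and do not establish about field data.

## The system and the experimental design

The package targets restoration experiments in estuarine salt marshes with
a three-level trophic chain: migratory shorebirds → burrowing herbivorous
crabs → native marsh vegetation (a clonal sedge). Four treatments, each
replicated in eight 4 m² plots (32 plots total): a natural-recovery
control, a planting control, planting with shorebirds excluded (netting),
and planting with crab grazers removed to simulate historically high
shorebird predation. Twelve ecosystem functions are measured per plot in
the final year; bird, crab-burrow, and plant counts are recorded monthly.

## Ecosystem-function estimators

All estimators live in `marshcascade.functions`; units are part of each
docstring. Conventions that matter:

- **Primary production** = aboveground + belowground biomass (g m⁻²).
  Aboveground uses the ramet allometry M = 0.0004·H^1.72 (H in cm)
  evaluated at the plot's *mean* stem height, times ramet density.
  Belowground scales the mean per-core dry mass by the 11 cm core
  cross-section (π·0.055² m²). Macrofaunal wet mass is pooled over three
  such cores, hence scaled by three core areas.
- **Benefit transform.** Gypsum dissolution (hydrodynamic stress) and the
  Nemerow pollution index are "costs"; both are reoriented as
  −fᵢ + mean(top-3 f) across all plots. The top-3 mean (rather than the
  single maximum) damps sensitivity to one extreme plot. Consequences:
  the three largest-cost plots average exactly 0 on the benefit scale,
  values can be negative (plots above the top-3 mean), and the transform
  is rank-reversing. Negative outputs are retained; standardization
  downstream handles them (see below).
- **Sediment accretion** = (first − last mark-to-surface distance) /
  months, averaged over the three poles per plot; decreasing distance is
  accretion. Carbon burial = accretion × (SOC%/100 × bulk density) ×
  10⁴ cm² m⁻², in g C m⁻² mo⁻¹; N accumulation is identical with total N%.
  Bulk density = dry core mass / 100 cm³.
- **Litter decomposition.** k from the log-linear fit of Lₜ = L₀e^(−kt)
  with the intercept *fixed* at ln(10 g): the placed mass is known
  exactly, so freeing the intercept only inflates variance. A
  `fixed_intercept=False` variant is provided. Non-positive masses are
  floored at 10⁻⁶ g with a warning before the log.
- **Nemerow index.** Classical form over seven metals:
  P = √((mean(Pⱼ)² + max(Pⱼ)²)/2) with single-metal ratios Pⱼ = Cⱼ/Sⱼ.
  The default reference limits are agricultural-soil screening values
  (Cd 0.3, As 25, Pb 80, Zn 200, Cr 250, Cu 100, Ni 60 mg kg⁻¹) and are
  configurable; site-specific standards should be supplied when known.
- **N mineralization** may legitimately be negative (net immobilization);
  no floor is applied.

## Multifunctionality

Two standardizations, following common practice: the averaged index uses
percent-of-max (each function scaled so its best plot is 100), Hill-number
metrics use the 0–1 scale. Both are columnwise over all plots in the
dataset, so values are relative to the observed experiment, not absolute.

For a plot's standardized profile F₁..F₁₂, relative contributions
pᵢ = Fᵢ/ΣFᵢ feed the effective number of functions N^q (power-sum form for
q ≠ 1, Shannon limit exp(−Σp ln p) at q = 1, with 0·ln 0 ≡ 0). Effective
multifunctionality is ^qM_ef = N^q × A with A the plain mean of the
profile. Numerical conventions:

- Zero-valued functions contribute pᵢ = 0 and drop from the sums, so N⁰
  counts the functions provided at a positive level. On generated data
  the benefit columns each contain exactly one shifted-to-zero plot, so
  the mean N⁰ over 32 plots sits just below 12 — expected, not an error.
- Columns with negative entries (possible for net mineralization and the
  benefit transforms) are shifted per column to minimum 0 before the
  relative proportions are formed, with a logged warning; the relative-
  proportion formula requires non-negative inputs. Whether to shift or
  truncate was an open choice; shifting preserves rank and spacing.
- Default order grid q ∈ {0, 1, 2, 3, 4, 5}.
- The above/belowground partition follows the field convention of
  splitting primary production into its above- and belowground biomass
  components (4 aboveground + 9 belowground = 13 components); the
  function matrix carries the split as auxiliary columns used only by the
  partition subsets.

## Trophic effect sizes

LRR = ln X_P − ln X_E with the delta-method variance
S_E²/(N_E X_E²) + S_P²/(N_P X_P²). The monthly crab-exclusion effect uses
the reverse orientation (exclusion over control, positive = crab release)
and is flagged as such in its metadata; burrow counts are x + 1 shifted to
avoid non-positive means in zero-count months.

Pooling is DerSimonian–Laird: Q on fixed-effect weights, τ² by the moment
estimator, then inverse-variance weights 1/(vᵢ + τ²) and a normal-theory
95% CI. DL was chosen over REML for its closed form — every step is
directly testable; the implementation reproduces the R `metafor` reference
(method="DL") to 10⁻⁸ on fixed inputs. Meta-regression of monthly effects
on a moderator (e.g. monthly shorebird abundance) uses weighted least
squares with an additive between-month heterogeneity component estimated
by the method of moments from the first-stage inverse-variance fit — a
deliberate approximation to a full mixed-effects meta-regression (see
Limitations). A zero-variance (constant) moderator is degenerate and
returns slope 0 with infinite uncertainty rather than a singular solve.

The historical back-projection assumes crab suppression proportional to
shorebird abundance:
D_hist = D_C + [(D_C − D_E)/(p·N_now)]·(N_hist − N_now), where p is the
proportional footprint change between control and exclusion arms. A
negative result means historical predator abundance would have eliminated
the grazers; it is reported as-is.

## Treatment inference

- ANOVA + Tukey HSD (statsmodels' studentized-range p-values, verified in
  tests against direct `scipy.stats.studentized_range` computation), with
  compact letter displays via insert-and-absorb: split every letter
  containing a significant pair, absorb subset letters, order letters by
  descending group mean. Groups share a letter exactly when not
  significantly different.
- Rank-sum (Mann–Whitney/Wilcoxon) pairwise tests for skewed responses
  (primary and secondary production), Bonferroni-adjusted
  (p_adj = min(1, m·p)); exact null distribution for tie-free samples
  below n = 8 per group, normal approximation with tie correction
  otherwise.
- Pairwise proportion tests as 2×2 chi-square with Yates continuity
  correction — conservative by construction (simulated size ≈3% at
  nominal 5% with ~100 trials per arm); this matches the conventional
  pairwise-proportion default.
- Model selection between linear and quadratic OLS by
  AICc = AIC + 2k(k+1)/(n−k−1) with k counting mean parameters plus the
  error variance.
- GLMMs (Gamma/Poisson with plot as a random effect) are **not**
  implemented: repeated-measures structure is handled by per-month tests
  plus the meta-regression above. The tidy effect and series tables are
  the data contract for delegating to an external mixed-model backend.

## Synthetic-data generator

The generator (`marshcascade.synthetic`) emulates the experiment's
*statistical* structure, not its mechanism. Generation is function-first:
per plot, a target value for each of the 12 functions is drawn around
baseline × treatment multiplier, and raw measurements are constructed so
the estimators recover the target exactly (heights from inverted
allometry, SOC% from inverted burial arithmetic, litter masses from the
exact exponential, etc.). Within-plot measurement scatter is recentred so
plot means are exact; all between-plot variation enters through the
target draw.

Key defaults (the study conditions; all configurable):

- **Effect multipliers** per treatment, relative to planting control, set
  to the experiment's reported percentage contrasts — exclusion:
  accretion 0.73, C burial 0.58, N accumulation 0.63, metal reduction
  0.26, respiration 2.61; predation simulation: secondary production
  2.83, wave 1.75, accretion 1.50, respiration 4.47, mineralization 1.15,
  litter 1.09, C burial 1.73, N accumulation 1.64, metal reduction 1.59;
  1.0 elsewhere. Primary production under predation simulation is set to
  8.0, an order-of-magnitude choice reflecting successful vegetation
  establishment (several-fold plant-density increase) where the grazed
  arms stay near baseline.
- **Baselines** are order-of-magnitude plausible constants (e.g.
  accretion 0.4 cm mo⁻¹, C burial 35 g C m⁻² mo⁻¹, k 0.25 mo⁻¹); all
  relative analyses are invariant to them.
- **Noise.** Ordinary functions: multiplicative lognormal with CV 0.15
  (mean-preserving). The two benefit-scale functions use zero-anchored
  Gamma noise (default CV 1). This is deliberate: the benefit transform
  forces every derived column's three smallest values to average exactly
  zero, so a realistic benefit-scale column must reach toward zero.
  A strictly positive, narrow target distribution would reappear after
  derivation shifted down by its bottom-3 mean, distorting treatment
  ratios; with the zero-anchored draw the shift is ~3% of the mean and
  multiplicative treatment contrasts survive derivation.
- **Crab burrows**: Poisson counts with log-mean = ln(8) + seasonal
  offset + exclusion·(0.80 + 1.60·birds_m/max birds). The intercept and
  coupling are calibrated so the pipeline's own monthly effect-size
  estimate shows ~68% mean and ~90% peak-season crab suppression by
  shorebirds; the positive coupling makes the exclusion effect track the
  spring/autumn migration peaks in the bird profile. The
  predation-simulation arm is generated at a fixed low rate (crabs
  actively removed) and is excluded from tethering.
- **Plants**: 9 clumps × 15 ramets planted; linear first-week change at
  −6 (control), −8.94 (exclusion, 49% faster loss), +2 (predation
  simulation) ramets day⁻¹; thereafter grazed arms decline to zero and
  the predation arm grows logistically toward ~8× the planting density.
  Counts carry Poisson observation noise.
- **Seeding.** All randomness flows from one seed through
  `numpy.random.SeedSequence` spawn keys indexed by (treatment,
  replicate[, month]); adding replicates, treatments, or months never
  disturbs existing draws. An optional mask reproduces a two-month
  observation gap (Feb–Mar 2020).

A companion generator produces the shorebird-mimic (non-consumptive cue)
experiment: 3 treatments × 8 plots, weekly Poisson burrow counts, with the
mimic arm's mean decaying as exp(−0.8·week) and both controls stationary.

**What passing tests show — and don't.** Parameter-recovery and type-I
error results on generated data validate the *estimators and pipeline
plumbing* under the generator's assumptions (independent plots, known
noise families, multiplicative treatment effects, exact estimator
inversion). Field data add spatial correlation among plots, measurement
error that does not cancel within plots, non-multiplicative treatment
responses, and mechanistic coupling between vegetation, crabs, and
functions that the generator deliberately omits (plot plant trajectories
and plot function values are drawn independently). Results on real tables
therefore inherit none of the synthetic guarantees beyond correctness of
the arithmetic.

## Problem sizes and numerical tolerances

The test suite and the reproduction script size their simulation studies
as follows: 500 experiments for percent-change recovery (|bias| < 1
percentage point on −20%/+61% generating effects), 2000 replicates for
type-I error (accepted band 3.5–6.5% at nominal 5%; 2–6.5% for the
conservative continuity-corrected proportion test), 2000 replicates for
DL CI coverage (accepted 93–97%), 4000 draws for the delta-method
variance check (±10%). Hill-number identities are checked to 10⁻⁹
(relative, two-sided central evaluation at q = 1 ± 10⁻⁶, which sits at the
floating-point floor imposed by the 1/(1−q) exponent). Exact estimator
arithmetic (decomposition k, carbon burial, benefit transform, Nemerow) is
checked to 10⁻¹² or printed precision.

## Known limitations

- Meta-regression approximates the month random effect by residual
  method-of-moments heterogeneity; a full mixed-effects meta-regression
  (or GLMM) may give different standard errors on strongly unbalanced
  series.
- The benefit transform ties every plot's score to the current dataset's
  top-3 plots; scores are not comparable across datasets.
- Percent-of-max standardization is sensitive to the single best plot per
  function; with n = 32 this is accepted, matching field practice.
- The generator draws the 12 function targets independently within plot;
  real functions are correlated through shared drivers. Spearman-matrix
  outputs on synthetic data are therefore near zero off-diagonal by
  construction.
- Tethering outcomes are generated per plot as a single binomial; daily
  survival structure within the week is not modelled.
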