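# Methods

This note documents the models, conventions and numerical choices behind
`ecoislands`, and what the synthetic data can and cannot say about real
field campaigns.

## Experimental design generator

`design.build_design` reproduces the factorial random-partitions layout:
four island area classes (25, 100, 400, 1600 m²; square plots), and within
each area class one unplanted island plus partitions of the six-species
pool into groups of size 1, 2, 3 and 6 — so every species appears exactly
once per diversity level per area class — giving 13 islands per area class,
52 islands (2.7625 ha) and four 100 m² controls.  The species-to-group
assignment is the only random element and is drawn from the seeded RNG.

Per-plot palm counts are not published for the original experiment, so the
generator derives them from the conventional planting density: initial
palms = round(A · 120/10 000 · 1.3), where the 1.3 layout factor reflects
that square plot footprints cut across the triangular planting grid and
hold somewhat more palms than area × density; 40 % of initial palms are
felled (at least one for islands ≥ 100 m², none in controls).  Adjacent
palms (position 1) are perimeter-proportional: round(4·edge / 9 m), the
9 m spacing matching a 120/ha triangular grid.  These choices give ≈ 270
remaining palms inside islands, the right order of magnitude for a
campaign measuring ~214 island palms, and they stay fixed across the
package's analyses.

## Synthetic data model

The generator encodes the causal skeleton the downstream analysis assumes:

- latent structural complexity pc1 = β_div·z(log(div+1)) + √(1−β²)·ε₁,
- latent tree dominance     pc2 = β_area·z(log edge)   + √(1−β²)·ε₂,

with β_div = β_area = 0.6 by default.  Both disturbances are drawn
orthogonal *in sample* to the treatment drivers and to each other
(residualized and rescaled to unit sd).  This conditional simulation makes
the encoded path model hold exactly at n = 56: standardized paths equal
their configured values up to estimation noise, the principal components
of the structure panel align with the generating latents instead of
rotating with finite-sample latent correlation, and d-separation claims
are true by construction.  Consequence: Monte-Carlo calibration results
measure the inference machinery, not finite-sample rotation artefacts.

Each indicator is direct island/area/diversity effects plus mediated
effects through the latents plus unit-sd noise, mapped affinely to natural
units.  Defaults give every functioning indicator a +1 sd island benefit
with varied, modest mediation mixes (|β| ≤ 0.35), keeping pairwise
indicator correlations below the 0.7 clustering cutoff.  Tree growth and
litter input share their treatment signal and have residuals correlated at
0.9 — the deliberately redundant pair the pre-selection must catch.

Raw streams emulated for the derivation stages:

- **Palm yields** (kg/palm/yr): reference palms ~ N(150, 20²); inside
  palms shifted −10 (reduced management); one palm per island at each
  adjacent position 1–3, with the +15 kg spillover confined to position 1;
  34 reference palms.
- **Temperature**: 180 days × 8 near-3-hourly readings per plot.  A strict
  3-h grid from midnight cannot contain both the 07:00 and the 15:00
  readings that define the daily amplitude, so the grid is
  (0, 3, 7, 9, 12, 15, 18, 21) h with a half-sine diurnal course peaking
  at 15:00.  Plot amplitude = 9.0 − 1.5·island − 0.8·pc1 + noise (°C).
- **Litter traps**: 4 traps × 24 semi-monthly dates; per-trap mass backs
  out a plot-level annual target (350 + 120·signal g/m²/yr) with 5 %
  trap-level noise.
- **Abundances** (10 taxa): log-normal ranked species-abundance
  distributions (σ = 1.2), Poisson-sampled per plot; total intensity rises
  with a composite treatment signal (abundance effect 0.35 per sd) and a
  tilt exponent flattens relative abundances in treated plots (evenness
  effect 0.25), so richness and evenness both respond.  Tree counts follow
  planted diversity and island size; controls hold few tree individuals.
- **Structure panel**: 12 variables as noisy loadings of the two latents,
  the two loading columns kept near-orthogonal with the pc1 block slightly
  stronger, so PC1 is the complexity axis and PC2 the dominance axis.

What the generator does **not** emulate: spatial autocorrelation between
plots, temporal yield dynamics beyond one aggregated year, zero-inflation
and sequencing-depth artefacts in the molecular taxa, device-specific
measurement error, or non-linear treatment responses.  A green suite
therefore shows the estimators and pipeline are correct under the assumed
data-generating process, not that the field conclusions themselves are
reproduced.

## Diversity

Hill numbers use 0·ln 0 ≡ 0 for q = 1.  Rarefaction to m individuals:
exact hypergeometric expectation Σᵢ[1 − C(n−nᵢ, m)/C(n, m)] for q = 0
(computed in log-gamma space), seeded mean over without-replacement
resamples (default 1000) for q = 1, 2.  Requests beyond the sample size
return the observed value with a warning — extrapolation is out of scope.
Only trees are rarefied (m = 24, the median tree count per plot); other
taxa are sampled at constant effort.  Empty plot × taxon samples stay
missing and are never counted as passing a threshold downstream.

## Multidiversity and multifunctionality

Indicators are min–max scaled to [0, 1] per indicator over all plots
(biodiversity and functioning separately; all indicators pre-oriented so
higher = better — buffering enters as the negated amplitude, soil C:N and
bulk density as reciprocals, invasion resistance as 100 − cover).  The
threshold count per plot uses (t/100) × the mean of the indicator's three
highest values; because min–max scaling is affine and the top-3 mean
commutes with affine maps, computing maxima before or after scaling gives
identical counts (asserted by test).  The averaging alternative is the
per-plot mean of non-missing scaled indicators.

Pre-selection clusters indicators by average linkage on 1 − |Spearman ρ|,
cut at 0.3 (i.e. |ρ| ≥ 0.7 merges).  Within a cluster the member with the
lowest mean |ρ| against the whole panel is retained.  The cutoff is a
package default — the reference analyses of this design dropped tree
growth a priori after observing the tree-growth/litter cluster, and the
pipeline's `force_drop: [tree_growth]` default reproduces exactly that;
with pure clustering one member of the pair is dropped either way, leaving
19 of 20 indicators.

## Yield accounting

Y_in is the median over a plot's inside palms; Y_adj the mean over its
position-1 palms (the field protocol has one palm per position, the mean
generalizes it); positions 2–3 are ignored, as only position 1 shows
spillover.  The decomposition identity ΔY = Y_spill + Y_remain − Y_foregone
holds exactly by construction and is fuzz-tested.  Expansion factors
convert per-palm to per-area yield: 10 000 × neighbourhood count / area,
falling back to the conventional 120 palms/ha for plots unaffected by
thinning; the exact neighbourhood census definition is a local dialect and
is parameterized rather than hard-coded.  Yields are aggregated over one
year.

## Derived indicators

Formulas as printed above (README).  Two conventions worth noting:

- **Litter annualization**: per-date plot medians over traps, a 3-SD-
  around-the-median outlier rule computed over the whole campaign's
  plot-date values, mean retained mass × 24 collections / 0.25 m² trap
  area.  Dividing by trap area is the dimensionally consistent reading
  (g/trap → g/m²); a description that multiplies by trap area would yield
  g·m².  On clean synthetic data the outlier rule removes < 5 % of dates.
- **Total AGB**: tree masses are summed per plot; palm mass enters as the
  mean measured palm mass × local stand density scaled to the plot area —
  the dimensionally consistent reading of a per-plot biomass in t/ha
  (kg/m² × 10).  Necromass and understorey are excluded as negligible.

## Structure ordination

PCA is the eigendecomposition of the correlation matrix of the z-scored
12-variable panel (plots with missing entries are column-mean imputed and
flagged, keeping the 56-plot panel intact).  PCA signs are arbitrary, so
the axes are anchored: SSCI loads positively on PC1 (complexity), tree
cover positively on PC2 (dominance).  Scores are orthogonal by
construction; the first axis explains more variance than the second.

## Treatment models

The mixed model on the long plot × indicator table has fixed effects
island, log edge, log(div+1), indicator, all treatment × indicator
interactions, area × diversity and its indicator interaction, and a plot
random intercept (controls enter with 10 m edge and zero diversity;
responses unit-scaled).  Term F-tests use containment denominator df: a
term whose design columns are constant within plots is tested against
between-plot variation (df = #plots − #between-plot columns), others
against the within-plot residual.  In this balanced layout the containment
F coincides with the classical split-plot test, and the null rejection
rate of the treatment terms calibrates at the nominal 5 % (checked over
500 simulated nulls).  The indicator main effect itself is mildly
anti-conservative under per-indicator min–max scaling (scale factors are
data-dependent); it is a nuisance term here, not a treatment test.

## Piecewise SEM

Component models are OLS fits of outcome ~ log area + log diversity,
pc1 ~ log diversity, pc2 ~ log area, on the 52 islands.  Candidate paths
pc1 → outcome and pc2 → outcome are screened by modification tests —
candidates evaluated jointly, added one at a time by smallest P < 0.05,
re-tested.  Standardized coefficients are β·sd(x)/sd(y); indirect effects
are products of standardized paths along each mediation chain.  The global
test is Shipley's d-separation: the union basis set of a DAG contributes,
for each non-adjacent pair (u, v), the claim u ⊥ v | pa(u) ∪ pa(v), tested
as the t-test of u in the regression of the downstream variable;
exogenous–exogenous pairs are skipped (their correlation is free).
Fisher's C = −2Σln pᵢ ~ χ²(2k) under the model; AIC = C + 2K,
AICc = C + 2K·n/(n−K−1), BIC = C + K·ln n with K the number of regression
parameters across component models; pseudo-R² is the OLS R² per endogenous
variable.

Residual normality of each component model is gated by Shapiro–Wilk
(α = 0.05); failing responses are ordered-quantile transformed
(rank → Φ⁻¹((r−½)/n)) and refitted.  The same gate applies inside the
claim regressions so the global test judges the model on the scale it was
fitted on.  The transform is rank-based because the pipeline's outcomes
include bounded counts and ratios for which a single parametric family
would be arbitrary.

## Problem sizes and tolerances

Simulation checks use: 200 seeds for spillover and mediation recovery
(bias bound 0.05 standardized units), 500 seeds for the d-separation and
mixed-model type-I calibrations (binomial ±2 SE band around 0.05; the
eight simultaneous per-term checks use ±3 SE each plus a pooled ±0.02
band), 100 seeds for path-sign recovery through the ordination, and a
reduced 3-indicator panel for the mixed-model nulls.  Exhaustive
rarefaction oracles enumerate all subsamples for totals ≤ 12.  Exact
identities (yield decomposition, allometric formulas) are asserted to
1e-9 relative or better.
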