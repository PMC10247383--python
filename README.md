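# ecoislands

Analysis pipeline for tree-island restoration experiments in oil-palm
landscapes, aimed at ecologists studying biodiversity–ecosystem-functioning
relationships in enrichment plantings.  The package covers the full
quantitative chain of such an experiment: generating the factorial
random-partitions design and statistically realistic synthetic data,
computing Hill-number diversity and threshold-based multidiversity /
multifunctionality, accounting for oil-palm yield changes per island,
deriving formula-based ecosystem-function indicators (allometric biomass,
microclimate buffering, litter input, soil ratios, …), reducing vegetation
structure to ordination axes, and fitting treatment mixed models and
piecewise structural equation models.

## The experiment and the statistics

The design embeds 52 *tree islands* in a conventionally managed oil-palm
plantation, crossing island area A ∈ {25, 100, 400, 1600} m² with planted
tree diversity (0–6 species from a six-species pool, partitioned so every
species appears once per diversity level per area class), plus four 100 m²
conventionally managed control plots — 56 plots in all, with roughly 40 %
of within-island palms felled at establishment.

Core quantities:

- **Hill diversity** of order q: ^qD = (Σᵢ pᵢ^q)^{1/(1−q)} — q = 0 species
  richness, q = 1 exp(Shannon), q = 2 inverse Simpson; tree diversity is
  rarefied to m = 24 individuals (exact hypergeometric expectation for
  q = 0, seeded resampling for q = 1, 2).
- **Multidiversity / multifunctionality**: the number of unit-scaled
  biodiversity / functioning indicators in a plot exceeding t % of the
  landscape-level maximum (mean of the three highest values), swept over
  t = 1…99 %.  Redundant indicators are pre-selected out by hierarchical
  clustering on 1 − |Spearman ρ|; in the default configuration the
  tree-growth/litter-input pair loses its tree-growth member, leaving 19
  of 20 functioning indicators.
- **Per-island yield change**:
  ΔY_island = Y_spillover + Y_remain − Y_foregone with
  Y_foregone = N_felled·Y_ref, Y_remain = N_in·(Y_in − Y_ref),
  Y_spillover = N_adj·(Y_adj − Y_ref); Y_ref is the median reference-palm
  yield and only the directly adjacent palm (position 1) carries spillover.
- **Allometry**: AGB_tree = 0.0673·(ρ·DBH²·H)^0.976 (kg),
  AGB_palm = 71.797·H − 7.0872 (kg), plot basal-area increment
  Σ(π/4)(d₂² − d₁²)/A.
- **Inference**: linear mixed models with treatment × indicator interactions
  and a plot random intercept (containment-df F-tests); Kruskal–Wallis per
  indicator; Tukey comparisons of palm position classes; and piecewise SEM —
  outcome ~ log area + log diversity, complexity (PC1) ~ diversity,
  dominance (PC2) ~ area — with modification-index path addition,
  standardized coefficients, indirect effects as path products, and global
  fit by the d-separation test (Fisher's C = −2Σln pᵢ, df = 2k).

## Worked example

```bash
ecoislands all --seed 1 --out run1
cat run1/summary.json
```

selected output (seed 1):

```json
{
  "n_plots": 56,
  "n_islands": 52,
  "island_area_ha": 2.7625,
  "n_biodiversity_indicators": 10,
  "n_functioning_retained": 19,
  "headline_threshold_pct": 50,
  "multifunctionality_median_islands": 11.5,
  "multifunctionality_median_controls": 5.0,
  "multidiversity_q0_median_islands": 8.0,
  "multidiversity_q0_median_controls": 1.0,
  "delta_y_island_median_kg": -178.7
}
```

Reading: the generated design holds 52 islands (2.76 ha) plus 4 controls;
10 biodiversity indicators (one per taxon) and 19 retained functioning
indicators enter the aggregation.  At the 50 % threshold the median island
exceeds the threshold on 11.5 functioning indicators versus 5.0 in the
controls (8.0 vs 1.0 for species-richness multidiversity) — the simulated
restoration benefit — while the median island loses ≈ 179 kg of fresh
fruit bunches per year, mostly as foregone yield of the felled palms.  The
accompanying `sem_paths.csv` shows the fitted mediation structure; for
seed 1 the diversity → structural-complexity and area → tree-dominance
paths are recovered near their generating value of 0.6 (0.556 and 0.582)
and the multifunctionality model passes the d-separation test
(Fisher's C = 9.77, df = 8, P = 0.28).

Every stage can also be run separately (`ecoislands synth|indicators|
diversity|multimetrics|yield|infer`), reads/writes plain CSV in the run
directory, and is deterministic given the seed.

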