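# Methods

## Median-quadrant association

For a variable pair (x, y) over countries, the analysis uses only each
country's position relative to the median of the non-missing values of x
and of y, computed on that pair's own pairwise-complete subset (so
different comparisons may use different country subsets, and their Ns
differ when columns are incompletely observed). The 2×2 quadrant counts are
tested with the **uncorrected** Pearson chi-square on 1 df; no Yates
continuity correction is applied, because the uncorrected statistic is the
closed form the reference counts in `seaomega.datasets` reproduce
(11.0029, 9.75, 10.01, 7.02, 62.67, 10.63) and the correction would not.
The association's sign is not taken from the chi-square (which is
direction-blind) but from quadrant concordance: below–below plus
above–above against the discordant cells.

Tie handling is not standardized in this kind of compiled-table analysis,
so it is an explicit option:

* `strict_above` (default): a value is *above* iff strictly greater than
  the median; values equal to the median count below.
* `exclude_ties`: values equal to the median are dropped and reported.

`fbdg_status` is the one variable not median-split: it is dichotomized by
presence/absence of a seafood recommendation. By default both "no FBDG at
all" and "FBDG without a seafood recommendation" count as absence; the set
of statuses counted as presence is a parameter of `analyze_pair`.

Multiplicity is handled Bonferroni style: every result in an m-comparison
family carries `alpha_protected = family_alpha / m`, kept at full precision
(0.05/6 = 0.008333…; reports show the conventional rounding 0.008). A
degenerate table (zero row or column margin) is assigned χ² = 0, p = 1 with
a warning, and is never counted significant.

Two exact invariances follow from the rank-only construction and are
property-tested: any strictly increasing transform of either variable
leaves the table, χ² and direction unchanged; and negating one variable
(even n, no values at the median) swaps its labels, preserves χ² and flips
the direction. With odd n the observation sitting exactly at the median is
labelled *below* under either sign, so the negation symmetry is exact only
at even n — a consequence of the strict-above convention, documented rather
than hidden.

## Four-attribute index

Scores count strict threshold exceedances — GDP above, price rank below,
total fish above, percent marine above their medians — over the
complete-case set of countries with all four attributes observed (excluded
countries are reported). Medians are taken over that same complete-case set
by default; `medians="available_case"` switches to per-variable available
data. The score (0–4) is treated as a continuous response in a fixed-effects
one-way ANOVA across the four guideline groups (none / no recommendation /
recommendation with serving size / recommendation without); no ordinal model
is attempted. The ANOVA is delegated to `scipy.stats.f_oneway` and
cross-checked in the tests against a from-scratch sums-of-squares
computation to 1e-9. A design with a between-group contrast but zero
within-group variance reports F = ∞, p = 0; a design with no contrast at
all reports F = 0, p = 1.

## Dietary LCn-3 allocation

Per-species intake is (g/week ÷ 7) × (mg/100 g ÷ 100) mg/day on an
edible-weight basis, with no cooking-yield adjustment. When the listed
species cover only a fraction c of total consumption, the implied total is
listed/c and the residual mass total·(1−c) is imputed at the
consumption-weighted mean density of the listed species — so the residual's
LCn-3 share always equals its consumption share. Scaling to a
recommendation multiplies every entry's grams (listed and residual alike)
by target/total; scaling only the listed species would change the share
structure, and proportional scaling of the whole mix is the default because
it preserves the documented share-invariance (the residual is part of the
national mix being extended). Unit conversions use 1 oz = 28.3495 g; a
`guideline_constants` mode substitutes the rounded 8 oz = 226.7 g bridge
that US dietary guidance prints, under which 8 oz/week is 32.385… g/day
(32.4 at one-decimal presentation). Rounding happens only at presentation.

Conservation (species + residual = total), exact share-invariance under
scaling, and the low-density-staple property — whenever the most-consumed
species has the strictly lowest density, its LCn-3 share is strictly below
its consumption share — are property-tested over random profiles.

## Synthetic data

The country generator draws a latent standard-normal LCn-3 factor and, per
covariate, a latent z with correlation ρ = 2·sin(π·effect/6) to it — the
exact Spearman↔Pearson map for bivariate normals, so the configured
`effect` is the asymptotic rank correlation. Covariates are conditionally
independent given the LCn-3 factor (a one-factor copula; positive
semi-definite by construction). Marginals are free choices since only ranks
reach the quadrant method: GDP log-normal (log-mean 9.0 ≈ $8,100, log-sd
1.2), price as the ordinal rank permutation 1..n of its latent, total fish
supply Gamma(shape 2, scale 10) kg/capita/yr, percent marine 100·Beta(5, 2),
dietary LCn-3 normal(150, 120) mg/day truncated at 0 (global availability
is on the order of 150 mg EPA+DHA per capita per day), and serving-size
recommendations log-normal around ≈33 g/day with sd ≈17 g/day, matching the
published spread of FBDG serving sizes. Guideline categories come from
quantile thresholds of their own latent propensity, ordered
none < no-recommendation < recommendation-without-serving <
recommendation-with-serving, with default frequencies 37:37:65:27 out of
166. Default effects carry the sign pattern the analysis targets (price
−0.30; serving size +0.45, guideline presence +0.30, GDP +0.35, total fish
+0.60, percent marine +0.35). Missingness is injected independently per
cell (MCAR) at per-column rates; defaults emulate a survey observing
serving sizes for ~65, GDP for ~160 and price for ~146 of 166 countries.
The country identifier and guideline status are never missing. One
`numpy.random.default_rng(seed)` stream drives everything in a fixed column
order, so a (config, seed) pair is reproducible to the stored decimal text.

What the generator does **not** emulate: real geographic clustering,
reporting artefacts correlated with GDP, non-MCAR missingness (e.g. price
surveys skipping low-income countries), or any attempt to match actual
country values. Passing calibration on this generator therefore shows the
test chain is correct and near-nominal under its assumed structure, not
that the compiled real-world tables satisfy those assumptions.

The consumption generator ranks species by a perturbed power law
(share ∝ rank^−dominance, log-normal jitter, re-sorted), scales listed
grams so they sum to `top_coverage` (default 0.748) of a
`total_grams_per_week` (default 138.9 g — a realistic national weekly
per-capita intake), and assigns densities uniformly over the configured
range except that the staple draws from the lower third and the runner-up
from the upper third, guaranteeing the low-density-staple /
high-density-minority structure.

## Calibration choices and numerical notes

The null-scenario type-I study (all effects 0, n = 166, 2,000 replicate
tables, rejections pooled across the six-comparison family at an
unprotected α = 0.05) is expected slightly above nominal: the median split
at even n fixes both table margins at 83/83, making the null distribution
hypergeometric, under which the exact rejection rate of the uncorrected
chi-square is 6.2% at n = 166. The 5% level is approached only
asymptotically; the guideline-presence comparison, whose x margin is
random, sits closer to nominal. Pooling across the family was chosen to
reduce Monte-Carlo variance at the fixed replicate budget. Power against a
+0.6 rank-correlation effect at the protected 0.05/6 threshold is
essentially 1 at n = 166 (500 replicates).

The ANOVA permutation check asserts a Kolmogorov–Smirnov *distance* below
0.05 from uniformity over 2,000 label permutations rather than a formal KS
test: the discrete 0–4 response makes the F reference distribution only
approximate, and a formal test at n = 2,000 would flag that approximation
itself.

Problem sizes throughout (2,000 calibration replicates, 500 power
replicates, 1,000-table oracle sweeps) keep the full suite under a minute
on one CPU while leaving Monte-Carlo standard errors a few tenths of a
percentage point.

## Known limitations

* The quadrant test discards within-half rank information; it is less
  powerful than rank-correlation tests and was chosen for fidelity to the
  compiled-survey procedure, not efficiency.
* Country-level per-capita supply is not individual intake; the allocation
  model inherits that ecological limitation.
* The diet model tracks EPA+DHA only — no selenium, vitamins D/B12,
  methylmercury exposure, or population-subgroup adjustments.
* The reference quadrant counts are fixed published inputs; the survey's
  own ANOVA F value and the US shrimp/salmon percentages depend on compiled
  external datasets and are reproducible here only in structure
  (degrees of freedom, share inequalities), not numerically.
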