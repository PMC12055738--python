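# Methods

## Scoring model

A region's pillar score is a two-level average. Dimension scores are
unweighted means of their indicators; pillar scores are weighted means of
dimension scores with weights ω normalised over the *defined* dimensions.
In the default configuration every indicator is its own dimension with
ω = 1, so the pillar score is simply the mean of the pillar's non-missing
indicator values.

**Missing-value rule.** A missing indicator contributes nothing to the
numerator and is removed from the denominator, so the score is the mean of
the data the region actually has. A pillar score is undefined only when
every contributing indicator is missing; undefined scores are *flagged*
(NaN), never coerced to zero — coercion would conflate "no data" with
"worst performance" — and are excluded from quartile assignment and from
inference, while still counting in favourability denominators (they remain
regions of their zone).

**Weighted missing handling.** The unweighted rule generalises to weights
by normalising with the sum of weights over defined dimensions (Σω·dim /
Σω), which keeps the ω ≡ 1 case identical to the plain rule. This was a
genuinely open choice; the alternative (fixed normaliser N_d) would shrink
scores toward zero whenever a dimension is missing.

**Polarity.** Indicators whose high values are unfavourable can be marked
`inverse` (aggregated as 100 − x). The default is `direct` for every
indicator, because raw factsheet percentages are aggregated as published
and indicator directionality is configuration, not something the package
can infer. No other rescaling or normalisation is applied before
averaging.

## Quartile classification

Cutpoints default to the 25th/50th/75th percentiles of the defined scores
(numpy linear interpolation). Binning uses half-open intervals with ties
at a cutpoint going to the *lower* class (deterministic): Q1 ≤ c25 <
Q2 ≤ c50 < Q3 ≤ c75 < Q4. National quartile occupancy can deviate from
25% per bin under ties or alternative quantile definitions; since the
binning behind published occupancy shares is not always stated, the
classifier accepts explicit cutpoints so any alternative rule can be
reproduced verbatim rather than reverse-engineered.

## Favourability

favourability(y, z) = 100 · n_Q3∪Q4 / n_total per zone and pillar, rounded
to one decimal with halves away from zero (31.25 → 31.3; Python's banker's
rounding would give 31.2). The denominator is every region of the zone,
including regions with undefined scores.

## Inference

Regions missing any pillar score are excluded listwise (the multivariate
test needs complete response vectors). The joint test is Pillai's trace
(robust default among the four classical MANOVA statistics); per-pillar
one-way F tests are reported alongside with df = (k − 1, n − k) for k
zones. Pairwise zone contrasts use t statistics on the pooled
within-group mean square with n − k degrees of freedom; the Bonferroni
family is the C(k, 2) = 15 pairs within each pillar, matching the
per-dependent-variable convention of standard statistical packages. Mean
differences are reported as first zone minus second zone, pairs in
lexicographic order, so a negative entry means the first zone
underperforms. The WE→MHU regression is ordinary least squares at region
level (each region one point); a constant response is reported as slope 0
with R² = 0, and a constant predictor is an error.

## Synthetic generator

The generator emulates a factsheet-level survey export: region r in zone z
gets, for indicator j of pillar p,

value = clip(zone_mean[z, p] + offset_j + factor_{r,p} + ε_{r,j}, 0, 100)

- `offset_j ~ N(0, indicator_sd²)` drawn once per indicator — indicators
  sit at systematically different levels within a pillar;
- `factor_{r,p} ~ N(0, shared_factor_sd²)`, an optional per-(region,
  pillar) shared term inducing intra-pillar correlation (off by default —
  realistic inter-indicator correlation is unknown, so it is provided but
  unparameterised);
- `ε_{r,j} ~ N(0, region_sd²)` independent region noise;
- cells go missing independently at `missing_rate` (missingness is
  completely at random; no informative mechanism is modelled).

Clipping events are counted and surfaced so calibration runs can keep
means away from the bounds. Everything derives from one integer seed;
identical configs are bit-identical.

**Defaults.** Zone sizes C=6, E=8, N=17, NE=16, S=16, W=8 (71 regions,
matching the published zone totals and the (5, 65) ANOVA degrees of
freedom). The 22 indicators split MHU=8, WE=7, DC=7 — the true assignment
is not public, so the split is an arbitrary documented default and fully
configurable. Zone means were fixed once at values loosely echoing the
published zonal ordering (South strong everywhere, Northeast weak on MHU
despite mid-range WE, Central weak on WE and DC), with indicator_sd = 8,
region_sd = 6 and missing_rate = 0.02 as plausible factsheet-like noise
and missingness levels.

**What passing tests show — and don't.** The generator reproduces the
survey's *structure* (counts, ranges, zones, missingness), not its
dependence structure: indicators are conditionally independent given zone
and pillar, there is no survey design effect, no spatial correlation
between neighbouring zones, and no urban/rural systematic gap. Tests
passing on synthetic data therefore validate the pipeline's arithmetic and
calibration (type-I error, ordering recovery), not substantive conclusions
about real NFHS data. Published inferential values (F = 15.463 etc.,
R² = .166) depend on the full external factsheet and are not recomputable
from this repository; the pipeline accepts any user-supplied indicator CSV
for that purpose.

## Numerical choices

- Scores are kept at full float precision internally; rounding happens
  only at reporting (1 decimal for percentages, 2 for mean differences,
  3 for F statistics, all half-away-from-zero via `decimal`).
- Quartile cutpoints use numpy's linear-interpolation percentile.
- Degenerate inputs fail loudly: empty dimensions, all-zero weights,
  zones with fewer than two usable regions, zero within-group variance,
  constant predictors, non-ascending cutpoints.
- Monte-Carlo experiment sizes: the null-calibration run uses 1000
  replicates of the full 71×22 pipeline (rejection-rate standard error
  ≈ 0.007 at α = 0.05); the missingness-unbiasedness check uses 40
  replicates, sufficient for its ±1-point tolerance.

## Known limitations

- MANOVA assumptions (multivariate normality, homogeneity of covariance)
  are not diagnosed (no Box's M); with 71 regions in unequal zones the F
  tests are moderately robust, but users with real data should check.
- No effect sizes beyond mean differences and R².
- No survey weighting, microdata parsing, or map rendering; favourability
  outputs are tidy CSVs suitable for external choropleth tools.
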