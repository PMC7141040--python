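# Methods

## The estimand and the design

The experiment is cross-sectional: every treatment group is a distinct set
of animals, sacrificed once. Two day-0 baselines anchor the scale — intact
controls (C, t₀) and electroejaculated males (E, t₀) — and each recovery
group (E, t₁) is an independent sample held under one combination of
temperature (12/16 °C), food (ad libitum / deprived) and period (15/30 d).
The recovery index

RI(%) = (mean VDW(E,t₁) − mean VDW(E,t₀)) / (mean VDW(C,t₀) − mean VDW(E,t₀)) × 100

is therefore a functional of three group means; no within-animal change is
identifiable and none is modelled. Residual material left in the ducts
after electroejaculation is not subtracted. RI is scale- and
shift-invariant in the raw weights, may exceed 100 % (overcompensation)
and may be negative (net loss); it is reported as-is. The denominator
B must be positive: a depleted group at least as heavy as the control is a
degenerate baseline and an error, not a number.

The hepatosomatic index HSI(%) = hepatopancreas / whole-body dry weight ×
100 is computed per animal and analysed at the group level.

## Bootstrap and BCa intervals

Uncertainty in RI comes from stratified case resampling: each of B = 1,000
replicates resamples with replacement *within* each of the three groups,
preserving the original sizes, and re-evaluates RI. The groups are
independent samples of different animals, so pooled resampling would mix
design cells; the resampling unit is the animal. The two baseline groups
are shared across treatment cells within a replicate. Replicates whose
resampled denominator is ≤ 0 leave RI undefined; they are excluded and
counted (clamping would distort the tails), and more than 20 % of them
aborts the analysis as an unstable baseline.

Intervals are BCa. The bias correction is
z₀ = Φ⁻¹((#{θ* < θ̂} + ½ #{θ* = θ̂}) / B), with the proportion clamped to
[1/(B+1), B/(B+1)] so an extreme plug-in cannot produce an infinite normal
quantile. The acceleration is the usual jackknife skewness ratio
a = Σ(θ̄−θᵢ)³ / (6 [Σ(θ̄−θᵢ)²]^{3/2}) over delete-one values, each
observation deleted from its own group with the other groups intact
(grouped jackknife, matching the stratified functional); a = 0 when the
denominator vanishes. Adjusted quantile levels follow the standard BCa
formula and endpoints are empirical quantiles with linear order-statistic
interpolation — declared once and used everywhere, so results are
bit-reproducible. With z₀ = a = 0 the construction reduces exactly to the
percentile interval, which serves as an oracle in the tests. A fully
degenerate replicate distribution falls back to the point interval, flagged
as `percentile_fallback`.

Two recovery indices are "significantly different" only when their 95 %
intervals are disjoint; a shared endpoint counts as overlap. This
non-overlap rule is deliberately conservative relative to a two-sample
test.

## Permutation inference for HSI

The factorial analysis fits a full 2×2×2 linear model with sequential
(Type I) sums of squares in the fixed entry order time, temperature, food,
then the two-way interactions (time×temp, time×food, temp×food), then the
three-way term — the order in which the factorial table is reported.
Sequential SS are computed by projection: the design matrix is assembled
once per analysis, QR-factorised, and each term's SS is the squared norm
of its block of Qᵀy, so permuted responses reuse the same factorisation
(one matrix product per batch of permutations). On balanced designs the
main-effect SS are order-invariant; on unbalanced ones the order is part
of the reported model.

p-values come from unrestricted permutation of the raw response across all
records, with per-term statistic F. The estimator p = (b+1)/(m+1) (b =
permuted statistics ≥ observed, within a 10⁻⁹ relative tie tolerance) is
valid at any finite m and can never be 0. Each term stops sampling on its
own schedule: after at least 50 iterations, sampling ends once the binomial
standard error of p̂ drops below 0.1 p̂, else it continues to the cap
(default 5,000). This spends ~100 iterations on a term with p ≈ 0.5 and
drives small-p terms to the cap, which is the behaviour one wants from a
screening table. When the number of distinct response arrangements is at
most 20,000 the distribution is enumerated exhaustively (distinct multiset
permutations; for two-group contrasts, index splits) and p = b/m is exact,
the identity arrangement included.

Contrasts between a baseline cell and a comparison cell permute the pooled
values with statistic |mean difference|; the reported estimate is baseline
mean − comparison mean, so a group whose HSI rose above baseline carries a
negative estimate.

Classical companions delegate to standard least-squares machinery: the
one-way ANOVA F, OLS regression whose headline R² is the *adjusted* R²
(1 − (1−R²)(n−1)/(n−2), allowed to be negative), and a one-way ANCOVA
(factor fitted before the covariate, sequential SS). Bartlett's K² is
computed from its closed form and checked against an independent
implementation in the tests; Shapiro–Wilk normality delegates to a vetted
published routine.

## Synthetic studies

The generator draws each variable independently per cell from a normal
distribution truncated at zero by redraw (no point mass at zero, no
clipping); the hepatopancreas weight is redrawn while it exceeds the body
weight. Each cell consumes its own substream of the master seed, split by
cell index, so appending a cell never perturbs existing cells' draws.

Defaults encode the study design: baselines 84 ± 4 and 52 ± 4 mg
(mean ± SE at n = 4, hence within-cell SD 8 mg, used for every VDW cell);
n = 5 per recovery cell except n = 4 in the two 30 d/16 °C cells; carapace
length from one common distribution (98.6 mm, SD 5) for all cells, the
design having found no size differences. HSI is induced through organ and
body weights (body 10 g, SD 0.8) rather than drawn directly, so the HSI
pipeline is exercised end-to-end; the hepatopancreas SD is backed out of a
target HSI SD via the CV decomposition cv²(HSI) ≈ cv²(hep) + cv²(body).
Recovery-cell VDW means follow the reported trajectory — 15 d: 30 %
(12 °C fed), 5 % (12 °C deprived), 100 % (16 °C fed), 55 % (16 °C
deprived); 30 d: 100 % everywhere except 165 % at 16 °C deprived. The
30-day HSI means are the reported 6.0/8.5/4.1/4.6 %; the unreported 15-day
means are recovered from the contrast estimates under the
baseline-minus-comparison sign convention (6.0 − estimate), which
reproduces every reported 30-day mean exactly.

What the generator does *not* emulate: within-animal correlation between
VDW and body size (none was detected in the source system; variables are
drawn independently), non-normal within-group variation, any seasonal
structure, and measurement error beyond the normal noise. Passing tests on
synthetic data therefore demonstrate the statistical machinery under the
design's sample sizes and spreads, not distributional robustness on real
measurements.

## Numerical choices and simulation sizes

- Quantile rule: linear interpolation, everywhere.
- Tie handling: half-weight for exact ties in z₀; 10⁻⁹ relative tolerance
  for permutation-statistic ties.
- Per-stage seeds in the pipeline derive from the master seed and a fixed
  stage tag (CRC-32), so re-ordering analyses leaves every stream intact,
  and the JSON manifest alone suffices to reproduce any stochastic result.
- Calibration simulations use 1,000 studies for interval coverage and 500
  for null rejection (the acceptance script uses 400/200), sizes at which
  binomial noise is a few percent — chosen as the package's own balance of
  precision against runtime.

## Known limitations

- **Small-sample interval coverage.** At the design's group sizes
  (4/4/5), 95 % BCa intervals for RI cover the truth in ≈ 86 % of
  simulated studies, rising to ≈ 92 % at n = 10 and ≈ 95 % at n = 20. This
  is the familiar narrowness of the nonparametric bootstrap at tiny n (the
  resampled mean's variance carries a factor (n−1)/n), not an
  implementation artefact: on identical data the endpoints agree with the
  standard R `boot`/`boot.ci` implementation to ~0.1 RI points, and that
  implementation shows the same ≈ 85 % coverage under the same conditions.
  Non-overlap decisions inherit this anticonservatism at day-0-sized
  groups.
- Permutation ANOVA uses unrestricted response permutation; specialised
  residual-permutation schemes for testing interactions in the presence of
  large main effects are out of scope. Under a global null the tests are
  exact up to Monte-Carlo noise.
- The non-overlap rule is a decision heuristic, not a hypothesis test with
  a controlled error rate.
- No multiple-testing correction is applied across contrasts, matching the
  analysis the pipeline reproduces.
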