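# Methods

`sibloc` simulates and analyses the consequences of inaccurate
retrospectively reported birth locations. Its three components are (1) a
synthetic sibling cohort whose reported birth locations mix household moves
with reporting error, (2) the discordance regression that decomposes the
two, and (3) Monte Carlo machinery quantifying the estimation biases the
reporting error induces in location-linked exposure regressions.

## The discordance decomposition

For each two-sibling family s, the indicator y_s = 1 when the two reported
birth locations differ under a chosen definition (different parish /
district / county, or coordinates more than d km apart). The linear
probability model

    P(y_s = 1 | agegap_s) = alpha + beta * agegap_s

attributes the age-gap gradient to household moves (annual move probability
q = beta: longer birth spacing, more opportunity to move) and the intercept
to reporting error: twins share a birth location by construction, so their
discordance can only be error. With per-report error probability p,
independent across the two reports, the pair error probability is
2p - p^2, hence

    p_hat = 1 - sqrt(1 - alpha_hat),
    se(p_hat) = se(alpha_hat) / (2 sqrt(1 - alpha_hat))   (delta method).

Fits use OLS with HC1 heteroskedasticity-robust standard errors (the
conventional default for linear probability models; the flavour is a
package choice). The same inversion applies to repeat reports of one
individual, where moves cannot contribute.

The identifying assumptions: concordant pairs are correct; siblings grew up
together; the move probability is linear in the age gap; errors are
equiprobable, mutually independent within pairs and independent of the age
gap. A Gaussian-copula error correlation is available
(`sibling_error_correlation`) to probe the independence assumption.

## The synthetic cohort as the estimand's data-generating process

The generator realises the decomposition the regression estimates, i.e.
move- and error-induced discordance are disjoint events:

1. Age gaps: a twin point mass (227/18,479 ~ 1.23%) plus a discretised
   gamma (shape 2) in months, truncated to [9 months, 27 years], with
   overall mean 4.5 years. The gamma shape (hence the SD, ~3.2 years) is a
   modelling choice; only the range, mean and twin count are pinned down.
2. Reporting errors: each report is wrong with probability p (default
   0.283 at the 1-km cell level); wrong reports are displaced by the error
   kernel.
3. Moves: drawn among error-free pairs with probability
   q * gap / (1 - (2p - p^2)), which preserves the marginal move
   probability q * gap exactly while making
   P(y = 1 | gap) = (2p - p^2) + q * gap exactly additive. Under fully
   independent mechanisms the union term -e*m would shrink the fitted
   slope to q(1 - 2p + p^2) (~half of q at the default p), i.e. the
   regression would not recover the parameter it defines; the disjoint
   construction keeps generator and estimand consistent at both margins.

A move relocates the second (younger) sibling's true birth cell; correct
reports always equal the sibling's own true cell.

### Displacement kernels

Neither the error nor the move displacement law is identified beyond the
distance profile of the discordance table, so both are calibrated mixture
surrogates:

* Error kernel: three isotropic 2-D exponential components (radial
  distance Gamma(2, s), s = 1.85 / 8.77 / 22.2 km, weights
  0.696 / 0.248 / 0.056) plus a 10.1% uniform-cell long-range component,
  snapped to the nearest different cell. Two free parameters (one scale +
  one long share) provably cannot match the observed decay between 5, 10,
  30 and 50 km simultaneously; three components can. The calibration
  targets were the conditional displacement shares
  P(>d | error) = {0.484, 0.293, 0.156, 0.120} for d = {5, 10, 30, 50} km
  and the realized level-specific error probabilities (parish 0.168,
  district 0.158, county 0.064). All distance shares are met within 0.02.
  The realized district share (0.150) sits ~0.008 below its target: with
  equal-size rectangular districts, short errors cross boundaries somewhat
  less often than on the irregular, population-clustered historical map,
  and the two targets cannot both be closed without breaking the distance
  profile. The effect on the district-level bias results is about 1 pp.
* Move kernel: two exponential components (2.4 and 65 km, weights
  0.47 / 0.53) plus a 17.5% uniform component, giving ~50% of moves beyond
  50 km and ~76% crossing a district boundary.

### Geography

An all-land rectangular tiling of 1-km cells, nested into parishes (9x10
km), districts (2 parishes, 18x10 km), counties (14 districts, 36x70 km),
98 counties in a 14x7 arrangement: 1,372 districts and 2,744 parishes over
~247,000 km^2, matching the historical 1951 hierarchy in unit counts and
mean unit areas. Because the map is all land, the midpoint of two reported
locations is simply snapped to the nearest cell (no coastline handling).
Spatial weights are queen contiguity at every level, row-standardised; a
single-unit level receives a unit self-weight. The reduced-extent variant
(12 counties, ~30,000 cells) keeps the unit sizes and is used for
cell-level simulations, where only the local geometry matters; its smaller
extent shortens the uniform long-range jumps, which mildly compresses the
>30/>50 km distance tails but leaves level-crossing rates essentially
unchanged.

## Exposure surfaces

Unit-level fields follow a spatial autoregressive model
S = (I - rho W)^{-1} eps (iid standard normal innovations), solved by
sparse LU for small unit sets and by a truncated Neumann series (tolerance
1e-8) at the cell level. Year-month effects T are iid standard normal with
no temporal autocorrelation. The exposure is
V = sqrt(k) T + sqrt(1-k) S with both parts standardised, then
re-standardised over the person-level evaluation population (the bias
algebra operates on person-level variance, so moments are person-weighted,
not unit-weighted). Ten independent fields per (level, rho) are simulated
and repetitions are split across them, so no single field draw drives a
result. Moran's I (standard closed form on the sparse weights) is the
spatial-autocorrelation diagnostic; on this lattice the replicate-averaged
district-level I is ~0.78 at rho = 0.95 and >0.8 at rho = 0.975, which is
why the trait analyses default to rho = 0.975.

## Attenuation Monte Carlo

Conditioning on reported discordance at the analysis level, each
discordant pair is error-affected with probability
(2p - p^2) / (q * gap + 2p - p^2); error-affected pairs have both reports
wrong with probability p^2/(2p - p^2), otherwise a random sibling. The
true exposure evaluates the surface at the sibling's reported location
(own error only), the snapped midpoint (both wrong) or the own reported
location (no error), always at the individual's own birth year-month; the
observed exposure is always the own-report value. Outcomes are
Y = X_true + N(0,1) with X_true standardised, so the true slope is 1.
Bias is 100 (b1 - b2)/b1 between the true- and observed-exposure slopes,
reported positive for attenuation, with b1 (not the known truth) in the
denominator for robustness to finite-sample signal noise. The sibling
fixed-effects version demeans within pairs. Monte Carlo SEs are the SD of
per-repetition biases over sqrt(reps); they understate between-field
variation slightly, which is why headline points use 20 fields x 40
repetitions.

At (rho = 0, k = 0) the OLS bias is, to first order, the share of
individuals carrying an assigned error (~15-16% at district level); the
sibling-FE bias is the error share of within-pair exposure variance,
(2p - p^2)/((2p - p^2) + q * mean gap) ~ 87.8% - the closed-form oracles
the tests cross-check. The simulated district OLS point (~14.6%) sits
about 1.9 pp below the ~16.5% reference value; the gap traces to the
slightly lower realized district discordance share (above) and to
both-error midpoints falling inside the erroneous sibling's own district
on the regular geometry.

ORIV (obviously related instrumental variables) stacks the data with the
two siblings' report-based exposures swapped and instruments one with the
other. Under injected classical error it restores the slope to 1; under
the location-error process it does not - and on this design the residual
bias is *upward* (~1.2 at rho = 0, k = 0), because for single-error
siblings the true exposure is by construction the sibling-report exposure,
so the instrument enters the structural equation. The package reports the
ORIV point estimate only; stacked SEs are out of scope.

## Fixed-effect-control bias

Here X is clean but the district fixed-effect controls are mismeasured:
mu_d is a district SAR field scaled by sigma_mu, X = (r mu_d/sigma_mu +
sqrt(1-r^2) eta) sigma_x (per individual, with sigma_x = 1), Y = beta X +
mu_d + eps, and district errors are assigned exactly as above (p = 0.158,
q = 0.009). Estimation is by within-district demeaning (identical
estimand to explicit dummies, much faster); singleton districts would be
dropped with a logged count. The bias beta2 - beta1 (observed- minus
true-district controls) is reported in units of sigma_mu/sigma_x, in which
it collapses across sigma ratios; it carries the sign of r, shrinks with
rho, vanishes at r = 0 and persists at beta = 0. Default 250 repetitions
per configuration, 25 per each of ten shared fields.

## Trait correlation by discordance distance

The genetic-PC analog is an *inherited* trait: a district-level SAR field
(rho = 0.975) evaluated at the family's origin cell - the older sibling's
true birth cell - shared by both siblings, plus iid noise (SD 1.0, chosen
so the concordant-bin correlation lands in the 0.4-0.6 range). Anchoring
at the origin rather than at each sibling's own birth cell is deliberate:
ancestry does not change when a household moves, so both reporting errors
and moves decouple the reported birth cell from the trait field. A
synthetic non-sibling reference population (10x the sibling sample,
uniform true cells, the same reporting-error process) provides per-cell
mean traits; the curve is the Pearson correlation between an individual's
trait and the reference mean at their reported cell, within bins of the
sibling pair's discordance distance (0, (0,10], (10,50], (50,100],
(100,200], >200 km; Fisher-z 95% CIs; bins under 10 observations are
flagged and reported without a CI). Cells without reference residents drop
their individuals with a logged count. With both mechanisms disabled every
pair is concordant and no decline can arise.

## Problem sizes and numerical choices

Default runs use 18,479 sibling pairs (36,958 individuals). Headline bias
points use 800 repetitions over 20 fields; grids use 200 repetitions over
10 fields on a 3x3 (rho, k) grid - enough for Monte Carlo SEs well under
0.2 pp. District- and parish-level analyses run on the full-scale
geography; cell-level analyses on the reduced-extent one. SAR power
series: tolerance 1e-8, at most 5,000 terms, error naming rho on
non-convergence. Midpoint snapping uses round-half-to-even on each
coordinate. Negative fitted intercepts clamp p_hat to 0 with a warning so
subgroup sweeps stay runnable; alpha >= 1 raises. All randomness flows
from one root seed through named, independent streams; identical seeds
give bit-identical outputs.

## What the synthetic data does and does not show

The generator reproduces the discordance table's marginal structure (level
and distance profiles, age-gap gradient) and the error-assignment design
exactly, so the bias results test the estimators under the stated
conditions. It does not emulate: irregular unit boundaries or the urban
concentration of the population (both raise boundary-crossing rates;
realized district-level biases sit ~1-2 pp below the references for this
reason); coastline effects on midpoints; fertility or birth-order
structure beyond two siblings; error heterogeneity across people or
places. Passing tests therefore show correctness of the estimators and
the stated calibration, not that real reporting error behaves like the
kernels.
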