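# Methods

## Data model and units

A core is an ordered stack of depth increments (half-open intervals
[depth_min, depth_max) in cm below the surface; the midpoint represents the
increment in regressions and interpolation). Canonical internal units are
Bq kg⁻¹ for activities (a `dpm/g` reader dialect converts by ×1000/60),
g cm⁻³ for dry bulk density, and LOI as a 0–1 mass fraction — LOI is
converted to percent only at the Craft-conversion boundary, so the 100×
error class cannot arise internally. Missing cells are NaN, never zero.

Cleaning proceeds in a fixed order: structural validation (depth ordering,
contiguity, value ranges, sd positivity; errors block dating), linear
interpolation of missing DBD/LOI against midpoint depth (edges extended by
nearest value; filled cells flagged), and a per-core LOI outlier filter that
blanks values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]. Quartiles use linear
interpolation between order statistics, the most widespread convention.
Cores with fewer than four LOI values skip the filter with a warning.

## Carbon stocks

OC% = 0.40·LOI% + 0.0025·LOI%², applied per increment (not to core-mean
LOI); carbon density ρ_C = DBD·OC/100 in gC cm⁻³. The 1 m stock is the
thickness-weighted mean ρ_C over increments within the top meter (an
increment straddling 100 cm is clipped) scaled to a 100 cm column and
converted to kgC m⁻² (×10). Cores shallower than 90 cm are ineligible;
cores of 90–100 cm are scaled by their mean density and flagged
`extrapolated` — the literal scaling rule rather than a depth-trend
extrapolation, which keeps the estimate transparent. Depth trends classify
cores by OLS of LOI% on midpoint depth with a two-sided t-test at α = 0.05
(the threshold is configurable; "significant" needs a number). Dataset
summaries average over cores, unweighted; site-level grouping is available
separately.

Reference constants (IPCC Tier I: 25.5 kgC m⁻² stock, 91 gC m⁻² yr⁻¹
removal factor) are annotation-only and never enter a computation.

## ¹³⁷Cs peak QC

The candidate peak is the maximum-activity increment, ties breaking to the
shallowest (younger, less compacted sediment; a deterministic rule is
needed). Three tests must all pass:

1. **Background**: Φ((peak − mean)/sd) ≥ 0.975 over the core's own
   activity distribution (peak included). A site-pooled reference can be
   passed explicitly; per-core is the default because it is self-contained.
   Zero spread degenerates to `peak > mean` with a warning.
2/3. **Adjacent separation** against the nearest measured shallower and
   deeper samples: the peak mean must exceed the neighbor mean and the two
   normal counting densities must share < 5% proportional overlapping area
   (∫min(φ₁,φ₂), computed by adaptive quadrature to 1e-6; for equal sds
   this equals 2·Φ(−|Δμ|/2σ), used as the test oracle). The alternative
   "2 standard deviations" description is treated as an approximation of
   the same criterion; both thresholds are configurable. A peak at a
   profile end fails (no neighbor can confirm a peak shape).

The accepted horizon is dated 1963 CE. Positional uncertainty is the
uniform distribution over the peak increment, moment-matched
(μ=(a+b)/2, σ=√((b−a)²/12)); the calendar-age uncertainty is the same
formula on the one-year span (σ ≈ 0.29 yr). Both are carried so the age-depth
model can combine them.

## ²¹⁰Pb model

Unsupported activity: per-sample total ²¹⁰Pb minus ²²⁶Ra with sds combined
in quadrature (`variable_radon`); where no radon exists, the mean of the two
deepest total-²¹⁰Pb measurements serves as the background (`tail_background`).

**Screening.** Two automated disturbance flags: *low activity* (max
unsupported < 3× the median counting sd — no resolvable signal) and *step
shape* (the best single-changepoint piecewise-constant fit of log
unsupported reduces residual variance by > 60% relative to a monotone
exponential fit — an abrupt-deposition signature). A manual override CSV
(core_id, include/exclude) takes precedence, mirroring how visual profile
evaluations are usually recorded.

**Supply prior.** Average annual atmospheric ²¹⁰Pb fallout is kriged
(ordinary kriging; exponential variogram γ(h) = nugget + sill(1 − e^{−h/r})
fitted to the empirical semivariogram by weighted least squares with
pair-count weights; great-circle distances in km) on the log scale at the
core location, then back-transformed: m = e^{μ+σ²/2}, v = m²(e^{σ²}−1).
The gamma shape uses the moment-matched m²/v by default — dimensionally the
correct form for a shape parameter — with the literal m/v reading available
via `convention="mean_over_var"`. The bundled fallout-point file is a
synthetic stand-in with plausible Northern-Hemisphere magnitudes
(~80–180 Bq m⁻² yr⁻¹); users supply their own points CSV for real work.
A singular kriging system falls back to inverse-distance weighting with a
warning.

**Model.** Sections of thickness Δc = 1 cm (configurable; changing Δc
changes the autocorrelation scale of the memory process, which is not
rescaled by a Δc power). Accretion slowness α₁ = ε₁,
α_j = w·α_{j−1} + (1−w)·ε_j, ε_j ~ Gamma(shape 1, mean 2.86 yr cm⁻¹);
w ~ Beta(6.6, 3.4); Φ ~ Gamma(shape from kriging, mean from kriging);
supported levels get one parameter per ²²⁶Ra sample with a weakly
informative Gamma(2, mean = Ra mean) prior and a normal ²²⁶Ra likelihood
(Pb-measured increments without radon use the mean supported level); in
tail mode a single supported parameter is centered on the deepest-two mean.
Ages are cumulative sums of α·Δc from the surface (surface age 0, the
collection year). Likelihood: total ²¹⁰Pb ~ Normal(expected unsupported +
supported, counting sd), with expected unsupported from CRS physics
(Φ/λ)(e^{−λt_top} − e^{−λt_bot})/mass, λ = ln2/22.3 yr⁻¹ (the standard
²¹⁰Pb half-life), slice mass = DBD × thickness × 10 kg m⁻². A Student-t(4)
likelihood is available for robustness. An accepted ¹³⁷Cs peak adds a
normal age term at its moment-matched depth, with the depth uncertainty
converted to age through the local α.

**Sampler.** Adaptive random-walk Metropolis-within-Gibbs in unconstrained
coordinates (log ε_j, logit w, log Φ, log supported — the ε
parameterization is identical to moving the α's but keeps every coordinate's
support fixed). Proposal scales adapt every 50 burn-in iterations toward
~30% acceptance and freeze afterwards; exactly 2,000 burn-in iterations are
discarded and 10,000 stored by default. Initialization is deterministic at
the prior means; the seed fully determines the output (the kernel is
numba-compiled for speed: ~3 s per core at default settings). Monotone
non-decreasing ages hold structurally because every α is positive.

A classical CRS implementation (t(z) = λ⁻¹ ln(I(0)/I(z)), slice-summed
inventory, optional exponential tail extrapolation of the inventory below
the deepest sample, Monte Carlo counting-error propagation) serves as an
independent oracle; on near-noise-free simulations the Bayesian posterior
median ages agree with it within combined uncertainties.

## Carbon accumulation rates

Per stored draw, the bottom is the depth where the age-depth curve crosses
the 100-yr horizon, by linear interpolation within sections (using the last
whole section instead would bias the bottom shallow by up to one section);
draws whose deepest age is younger than the horizon use their deepest point
and its actual age as the divisor, and are counted. The stock to the bottom
(clipped partial increment included) times 10⁴/age gives gC m⁻² yr⁻¹.
Credible intervals are equal-tailed 2.5–97.5% quantiles with the
median-unbiased estimator. Accretion over the horizon is depth-at-horizon /
horizon ×10 (mm yr⁻¹); its CV% = sd/mean × 100. Dataset means average
per-core posterior means, unweighted, matching the stocks convention.

## Simulator

The generator emulates: contiguous 1 cm increments to 1 m; LOI declining
asymptotically (0.081 + (0.195 − 0.081)e^{−0.03z}, the magnitudes typical
of California tidal marsh profiles) with additive noise truncated to (0,1);
DBD from ideal organic/mineral mixing 1/DBD = LOI/k₁ + (1−LOI)/k₂ with
self-packing densities k₁ = 0.085, k₂ = 1.99 g cm⁻³ (literature-standard
values, exposed as scenario parameters); total ²¹⁰Pb from CRS physics with
Φ = 150 Bq m⁻² yr⁻¹ over a 15 Bq kg⁻¹ supported level; a ¹³⁷Cs deposition
pulse (zero before 1954, triangular rise to 1963, 10-yr e-folding decline —
only the 1963 peak location matters downstream) mapped to depth through the
true ages; and multiplicative counting noise (CV 5%, sd floor 0.3 Bq kg⁻¹)
recorded as the reported counting error. Radionuclides are sampled every
2 cm to 40 cm (≈20 samples per core, the order of real campaigns).
Accretion is constant at 2.86 yr cm⁻¹ by default, or the same
gamma-autoregressive process the model uses as its prior. Truth records
(ages, Φ, noise-free stock, 100-yr CAR, 1963 depth) accompany every core.

Not emulated: spatial correlation between cores, decadal variability in
fallout, compaction, bioturbation/mixing, ¹⁴C, and non-steady supported
profiles. Passing recovery tests therefore demonstrates correctness of the
inference machinery under the model's own assumptions, not robustness to
field pathologies — the screening stage exists precisely because real
profiles violate them.

## Problem sizes and tolerances

Tests and the acceptance script run reduced MCMC sizes (typically 500–2,000
stored draws, 500–2,000 burn-in) and 25–100 simulation replicates; these
sizes give Monte Carlo errors comfortably below the tolerances asserted
(coverage thresholds at 80% against nominal 95%, oracle agreement within 2×
combined uncertainty, closed forms to 1e-6 or tighter). Quantile estimation
uses the median-unbiased estimator throughout. Degenerate inputs (zero
reference spread in the background test, missing neighbors at profile ends,
exhausted ²¹⁰Pb inventories, singular kriging systems) return the
documented conservative branch rather than raising, except where a result
would be meaningless (all-missing interpolation, inverted depths).

## Known limitations

- The sampler is a generic adaptive Metropolis-within-Gibbs, not the t-walk
  used by the published Plum software; posteriors agree in the regimes the
  tests cover but mixing efficiency differs.
- One supported-level parameter per ²²⁶Ra sample can be slow to mix on very
  densely sampled profiles.
- Kriging assumes second-order stationarity of log fallout; with very few
  points the variogram fit is weakly constrained.
- ¹³⁷Cs activities are not decay-corrected to the collection date, and only
  the 1963 peak (not the 1954 onset or Chernobyl) is detected.
- ¹⁴C columns are carried through I/O but never calibrated or used.
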