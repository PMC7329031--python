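# Methods

This note records the modelling choices, default parameters and numerical
conventions behind `paleodyn`, and what the synthetic experiments do and do
not demonstrate.

## Radiocarbon calibration

A date with measured age `a ± e` (¹⁴C yr BP) is calibrated against a curve
`(μ(θ), σ(θ))` on an annual cal BP grid. The density assigned to calendar
year y is the likelihood

    L(θ) = Normal( a ; μ(θ), sqrt(e² + σ(θ)²) )

integrated over the yearly cell `[y−0.5, y+0.5]` and normalized so the
density sums to one. Integration uses composite Simpson quadrature with four
sub-intervals per year on the linearly interpolated curve; because curve
knots sit on integer years, the quadrature panels never straddle a slope
break, and the result agrees with brute-force fine-grid integration to
better than 1e-8 for realistically smooth curves (curves whose within-year
¹⁴C slope stays in the range of published calibration curves). Evaluation is
restricted to the region where the standardized residual is below 8, which
truncates less than ~1e-15 of the mass; mass cut off by the *curve edge* is
detected and reported (warning or error, configurable).

Marine and mixed-diet samples use a blended curve: on the common annual grid

    μ_mix = (1−f)·μ_terr + f·(μ_mar + ΔR)
    σ_mix² = (1−f)²·σ_terr² + f²·(σ_mar² + σ_ΔR²)

with `f` the marine-carbon fraction of the diet and ΔR the local reservoir
offset (the Rapa Nui default is −83 ± 34 yr). When only δ¹³C is known, `f`
comes from linear interpolation between end-members (defaults −21‰ ↔ fully
terrestrial, −12‰ ↔ fully marine; configurable, since end-member choices
vary between studies).

Internally all grids are cal BP (present = 1950 CE); the CE convention
appears only on the series containers.

## SPD construction

- **Modern filter.** Dates whose median calibrated age falls below 125 cal BP
  are dropped before binning (they carry no pre-contact demographic signal).
- **Site binning.** Within a site, calibrated median ages are clustered by
  single linkage with cutoff = bin width (50 yr default): consecutive sorted
  medians closer than the cutoff share a bin. Each date is weighted by
  1/(bin size), so a heavily re-dated site counts once per 50-yr episode.
- **Summation.** Per-year SPD value = Σ weightᵢ · densityᵢ(year). Total mass
  equals the number of bins (asserted to 1e-6 in tests); no further
  normalization is applied, so SPD units are "bins".
- **Smoothing.** Centred 100-yr rolling mean; edges use the truncated
  (shrinking) window so the series keeps its length for the later interval
  resampling. This damps calibration-curve wiggle artefacts at the cost of
  blurring genuine decadal structure.
- **Interval series.** The demographic series takes the mean of the smoothed
  annual SPD over each 30-yr interval (t − 30, t], one value per step from
  890 CE. Interval means rather than point samples are used because the
  coarse series is meant to capture multi-generation trends, and means are
  less sensitive to residual annual noise. Model fitting is restricted to
  the 1100–1760 CE window (23 values, 22 growth rates): the earlier SPD is
  dominated by sparse-date noise and the post-1760 record by
  post-European-contact dynamics, which the resource-driven model does not
  attempt to describe.

## Monte-Carlo null test

A linear (or exponential) trend is fitted by OLS to the observed smoothed
SPD over the analysis window. Each simulation draws as many calendar years
as there are observed site bins with probability proportional to the fitted
trend (floored at a tiny positive value), back-simulates a ¹⁴C measurement
per year through the curve — `μ(θ)` plus curve noise plus a lab error
resampled from the observed error pool — recalibrates, and rebuilds the SPD
with the same summation and smoothing. The envelope takes per-year
order-statistic bounds rounded outward (`lower`/`higher` percentile methods),
so the two-simulation degenerate case still contains its own draws and a
fresh null draw falls outside a 95% envelope from n simulations with
probability ≈ (⌊0.025(n−1)⌋+1)·2/(n+1) ≈ 5%. The global p-value compares the
observed summed out-of-envelope exceedance against its simulated
distribution with the usual (1 + #{sim ≥ obs})/(n + 1) estimator.

## Growth-model fitting

The fitting target is the growth rate, not the abundance: residuals
`R_t − r_max(1 − N_{t−1}/K(F_{t−1}, C_{t−1}))` are minimized by
`scipy.optimize.least_squares` (TRF, analytic Jacobian). Covariates enter at
one 30-yr lag; pollen is linearly interpolated to the model grid, the annual
climate index is averaged within each interval, mirroring how the proxy
itself is an interval mean. K is linear in the covariates with a free
intercept in all forms; a no-intercept (proportional) variant is a config
option because a strictly linear R-vs-N/resource relationship implies
proportionality.

Start points: 20 deterministic Latin-hypercube samples over
r ∈ (0, 2], k0 ∈ (0.1, 4)·max N and covariate coefficients spanning
±2·max N / max |covariate|, plus one start obtained by solving the OLS fit of
R on (1, N, N·F, N·C) back to Ricker parameters (a first-order linearization
of the model). To keep 200-replicate studies fast, the starts are screened
by initial cost and the best ten are polished to convergence; the lowest
residual sum of squares wins, ties going to the earliest start. Non-positive
K during the search is handled by a smooth penalty (residuals inflated
proportionally to the K excursion below a small positive floor) rather than
hard rejection, which keeps the trust-region search stable.

The parameter covariance is the asymptotic Gauss–Newton estimate
`s²(JᵀJ)⁻¹` with `s² = RSS/(n − p)`. AICc is computed as
`n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with k counting the error variance
(k = p + 1), applied uniformly so model ranking is unaffected by the
convention; the additive likelihood constant is omitted. Akaike weights are
`exp(−Δᵢ/2)` normalized. The prediction coefficient
`R² = 1 − Σ(Ŷ−X)²/ Σ(X−mean X)²` is computed on the *full forward
simulation* from the first observed value (not one-step-ahead predictions),
matching the simulation protocol used for the trajectory figures; this is
the stricter of the two readings and can be negative.

Trajectory uncertainty: `n_iter` (default 10 000) parameter vectors drawn
from the multivariate normal of the estimates (eigenvalue-clipped to PSD),
each simulated forward, per-time percentile bounds at the requested level.
Draws that put K ≤ 0 anywhere on the horizon are rejected and counted; a
rejection rate above 50% raises an error suggesting reparameterization —
in the full pipeline that condition is recorded per model in the report
instead of aborting, because it is the expected outcome for a weakly
identified form (e.g. constant K on boom–bust data). The first point of a
band is the pinned initial condition and carries no parameter uncertainty,
so coverage experiments assess the remaining points.

## Vegetation regression

The pollen response is used as a raw percentage (an optional z-score flag
exists; the transformation used by the original pollen workflow is not fully
specified, and users should treat absolute coefficients accordingly).
Predictors are the mean SPD and mean climate index over the 30 years
preceding each pollen sample. Candidate term subsets {N}, {C}, {N, C},
{N, C, N×C} are fitted by OLS; the interaction is only admitted with both
main effects; ranking uses the same AICc convention as the growth models.

## Synthetic-data generator

The generator emulates the study system's shapes with known truth:

- **Palm pollen:** deterministic logistic decline, defaults 40% → 1% with
  midpoint 1400 CE and steepness 0.006 yr⁻¹, i.e. a gradual decline spanning
  roughly 1100–1700 CE like the sediment-core record.
- **Climate index:** linear trend with AR(1) noise, defaults −0.3 start,
  +0.1 per century (drought-ward drift), AR1 = 0.5, innovation sd 0.08.
- **Population:** Ricker trajectory on the 30-yr grid over 800–1800 CE,
  default truth `r_max = 0.45` per step (≈1.3%/yr at low density),
  palm-driven capacity `K = 1 + 0.15·F` (≈6.2 → 1.2 SPD units as the forest
  declines), start 0.5 — a boom–bust trajectory peaking near 1130 CE.
  Observation noise is multiplicative lognormal (default sd 0.05).
- **Dates:** calendar years sampled proportionally to population size,
  back-converted to ¹⁴C measurements through the bundled synthetic curve
  (smooth, strictly monotone, mild wiggles, generated by code — no real
  curve file ships with the package), lab errors uniform on 30–80 yr,
  sites assigned by a symmetric Dirichlet-multinomial over 95 sites;
  244 dates by default, matching the size of the real Rapa Nui compilation.

A second, cheaper replicate generator injects Gaussian noise (sd 0.02)
directly into the step growth rates on the 1100–1760 CE grid (22
observations); the recovery, selection and coverage studies run there, since
they probe the estimator rather than the radiocarbon layer. All stochastic
operations take explicit seeds; outputs are byte-identical under the same
seed.

What passing these experiments shows: the pipeline is internally consistent
(generator and fitter agree exactly without noise), approximately unbiased
at realistic noise, and its uncertainty statements are calibrated. What it
does not show: robustness to taphonomic loss, to research-intensity biases
in date accumulation, to pollen-count error or age-depth uncertainty in the
covariates, or to misspecified K forms — real compilations violate the
proxy assumption in ways the generator deliberately does not model.

## Problem sizes and numerical defaults

Simulation studies use 200 replicates (50 for the full radiocarbon loop,
where each replicate calibrates 244 dates), 1000 multivariate-normal draws
per band in the coverage study, and 200–300 Monte-Carlo null simulations;
these sizes give Monte-Carlo standard errors well inside the tolerances they
are compared against. Percentile bands at other sizes use the same
order-statistic conventions throughout. Degenerate inputs fail fast with
named errors: non-positive proxy values before the log transform, constant
predictors in regressions, series shorter than parameters + 3, AICc with
n ≤ k + 1, envelope levels outside [50, 100).

## Known limitations

- The SPD is a relative proxy; absolute population sizes, and any K in
  head-count units, are not identified.
- Site-bin down-weighting interacts with genuine density: strongly clustered
  dating of a real boom is partially absorbed into bins, which biases growth
  rates toward zero (visible in the exponential-recovery experiment when
  sites are few).
- The asymptotic covariance slightly underestimates uncertainty at n = 22;
  measured band coverage sits near 93–94% rather than 95%.
- Covariate measurement error is ignored; K-form selection conflates "palm
  matters" with "anything collinear with palm matters".
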