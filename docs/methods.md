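# Methods

## The estimation model

An acoustic-trawl survey observes, for each one-nautical-mile by 250 m
echo-integration interval, a nautical area scattering coefficient
`s_A` (NASC, m² n.mile⁻²). Biomass estimation proceeds in three stages.

**Allometry.** Individual krill wetmass follows a power law of total
length, `WW(TL) = a·TL^b` (WW in g, TL in mm). The fit minimises
`Σ(WW − a·TL^b)²` on the untransformed scale — deliberately not log-log
regression, which estimates the median rather than the mean response
under multiplicative error. Start values come from log-log OLS; the
optimiser is Levenberg–Marquardt (`scipy.optimize.curve_fit`, xtol/ftol
1e-12). Krill under 10 mm total length are excluded everywhere (they are
not reliably retained by the net or resolved acoustically). Parameter
uncertainty uses a non-parametric bootstrap (default 999 replicates)
resampling *trawls*, not individuals: krill within one trawl come from
one swarm or station and are strongly dependent, so the trawl is the
exchangeable unit. CVs are sd(replicates)/point-estimate; replicates that
fail to refit (degenerate resamples) are dropped, not imputed.

**Conversion factor.** With the pooled length frequency `fᵢ` at 1-mm
classes (matching the TS table's grid), the survey-wide factor is

    C = [Σ fᵢ·WW(lᵢ)] / [Σ fᵢ·σ_sp(lᵢ)] / 1852²,

where `σ_sp = 4π·10^(TS/10)` m² and TS comes from a 120 kHz
TS-at-length table, interpolated linearly in dB between grid points
(tables are dense — 1 mm steps — so the interpolation convention is
second-order; out-of-range lengths are an error, never extrapolated).
The `1/1852²` converts per-square-nautical-mile to per-square-metre, so
`ρ = s_A·C` is in g m⁻². A single survey-wide `C` is used: sparse trawl
coverage rarely supports per-stratum length frequencies, and pooling
eliminates temporal bias from krill growth over a multi-week survey.

**Design-based estimator.** Transects are the sampling units. Each
transect's effective length is

    L_j = coverage_weight_j × Σᵢ W_I,i

with coverage weight 0.5 for transects on the survey-area boundary (half
their effective coverage lies outside) and per-interval deviation
weights `W_I = (|ΔL| − |ΔL − ΔL̂|)/|ΔL|` comparing planned vs made-good
latitude change, snapped to 1 when the deviation is under 10%. Transect
density is the `W_I`-weighted mean of interval densities — an interval
that counts less toward length also counts less toward density. The
survey estimate is

    w_j  = L_j / mean(L),
    ρ̂   = Σ w_j ρ_j / Σ w_j,
    Var  = N/(N−1) · Σ w_j²(ρ_j − ρ̂)² / (Σ w_j)²,
    CV   = √Var / ρ̂,

the ratio-estimator variance with a finite-sample correction. Biomass is
`β̂ = ρ̂ × area` (1 g m⁻² ≡ 1 t km⁻²) with normal-theory bounds
`β̂(1 ∓ 1.96·CV)`, floored at zero. The 1.96 multiplier is a design
choice: it reproduces the published bounds convention, but at N = 6
transects it under-covers relative to a t quantile (coverage ≈ 89%
rather than 95% on a Gaussian field; the test suite checks coverage
against the 88–98% band appropriate for this design-based
approximation). Transects left without usable intervals after filtering
are dropped with a warning and N decremented.

## Day/night analysis

Day and night are civil: day iff the sun-centre's apparent elevation is
≥ −6° at the interval's start position and time. Elevation comes from
the NOAA solar position equations (Julian-century polynomials for solar
longitude/anomaly/eccentricity, equation of centre, apparent longitude,
corrected obliquity, declination, equation of time, hour angle) with the
standard atmospheric refraction correction; accuracy is a few hundredths
of a degree, far inside what twilight classification needs. Working from
the elevation predicate, not dawn/dusk event times, keeps polar dates
with no civil dusk well-defined.

Comparisons: a two-sample KS test (exact sup-ECDF statistic; asymptotic
Kolmogorov p with effective n = n₁n₂/(n₁+n₂) — appropriate at the
hundreds of intervals per period a survey yields) and a Welch
unequal-variance t-test with a Satterthwaite-df CI on the day−night mean
difference (the variance structure of zero-inflated densities differs
between periods, so the pooled-variance variant is not assumed). Swarm
encounter rates are total swarms over total distance per period, with a
CV across per-transect rates (the design's sampling unit). The swarm
depth trend uses locally weighted linear regression (tricube kernel,
default span 0.4) with case weights equal to swarm volumetric density,
so dense swarms pull the curve; the smoother is exact on linear data and
invariant to rescaling all weights.

## Latitudinal bands

Equal-height bands (default 0.63°, the reference box's latitudinal
extent) are anchored so one band coincides exactly with the box; the
rest tile northward, labelled A (north) to the box band. Assignment is
half-open `[south, north)`. Per band: presence fraction (percent of
intervals with ρ > 0) and conditional densities ρ[ρ>0] — together they
reconstruct the unconditional mean. Representativeness tests:
Kruskal–Wallis (midranks, tie-corrected) across bands plus the box, and
per-band KS and Welch tests of conditional densities against the box.
The between-band comparisons are unpaired Welch tests: the samples are
disjoint sets of intervals, so a paired design is not defined. Both raw
and Holm-adjusted p-values are reported; bands with fewer than two
conditional densities are flagged untestable rather than dropped.

## Synthetic surveys

The generator emulates a late-summer East Antarctic krill survey:

- **Layout.** Six meridional transects of 200 one-nautical-mile
  intervals (boundary transects coverage-weighted 0.5), vessel speed
  7.3 kn, lawnmower direction alternation, real UTC timestamps. Day
  labels are produced by running the package's own solar classifier on
  the generated positions/times, so the day fraction (~0.7–0.8 at these
  latitudes in February–March) emerges rather than being set.
- **Densities.** Zero-inflated lognormal: presence is Bernoulli (default
  0.5) and conditional density lognormal (default sdlog 1, right-skewed
  as swarm-driven data are), calibrated so the unconditional survey mean
  is 6.2 g m⁻² with a day−night mean difference of 4.8 g m⁻²
  (night-time krill above the transducer go unseen). Optional per-band
  presence and density scales create latitudinal structure; the
  reference box, spread over three days so its diel composition matches
  the main survey's, shares its own band's distribution by construction.
- **Swarms.** Poisson counts at 3.7 (day) and 1.0 (night) per nautical
  mile; day depths broad (truncated normal, mean 120 m, sd 60 m), night
  depths peaked near 25 m, both confined to the observable 15–250 m zone.
- **Trawls.** 34 trawls, 3,247 lengths from a two-component Gaussian
  mixture (means 36/49 mm, truncated at 10 mm) with small between-trawl
  mean shifts (sd 1.5 mm) providing cluster structure; 502 random
  individuals carry wetmass `a·TL^b·exp(ε)`, a = 1.71e-6, b = 3.41,
  ε ~ N(0, 0.2²).
- **TS table.** A smooth synthetic stand-in `TS = a0 + slope·log10(l)`
  on a 10–65 mm grid (defaults −127.45 dB, 34.85 dB/decade), monotone
  and of realistic magnitude; it is not a scattering-model output.
- **Closure.** NASC is back-computed from true density through the
  scenario's own conversion factor (true allometry + generated length
  frequency + TS table), so with all noise off the full pipeline returns
  the true mean density exactly; truth.json records every generating
  parameter plus derived truths.

What the generator does *not* emulate: spatial autocorrelation of the
density field (intervals are independent given their band and period),
sea-ice and bathymetry constraints on track, species mixtures, or
TS-model uncertainty. Passing tests therefore demonstrate correctness of
the estimation machinery under the stated sampling model, not robustness
to spatially structured fields — the design-based estimator's variance is
exact only under the independence the generator provides.

## Numerical choices and edge cases

- Problem sizes in the test suite: calibration runs use 1,000 replicate
  density fields on the 6×200-interval layout (bias within 2 Monte-Carlo
  SEs; CI coverage within 88–98%), band self-identification 500
  replicates, the estimator-vs-oracle check 1,000 random small
  instances, and the KS-vs-brute-force check every pair of multisets of
  size ≤ 4 over a 4-letter alphabet plus random samples to size 8.
- Untransformed NLS under multiplicative noise is noticeably less
  efficient than log-scale fitting: at n = 502 and σ_log = 0.2 the
  sampling sd of b̂ is ≈ 0.09 (2.6%). Tests bound recovery accordingly.
- CSV I/O uses `%.17g` floats and round-trip parsing so written surveys
  reload bit-exactly; report JSON is full precision, the human table is
  rounded to one decimal.
- Ties in KS samples are handled by right-continuous ECDFs evaluated at
  all pooled points; identical-everywhere Kruskal–Wallis input returns
  H = 0, p = 1 (a valid no-signal outcome, not an error).
- Single-row TS tables are accepted but only exact-length lookups are
  allowed; duplicate or non-monotone length grids are rejected.
- Out-of-division and out-of-band intervals are flagged and counted,
  never silently dropped; all-data vs day-only estimation is an explicit
  filter, applied before per-transect aggregation.
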