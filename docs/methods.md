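# Methods

## Model

The package implements the reduced General Unified Threshold model of
Survival (GUTS-RED), the standard toxicokinetic–toxicodynamic framework
for lethal effects of chemicals on aquatic animals. Toxicokinetics and
damage dynamics are lumped into one scaled-damage state `Dw(t)` in
exposure-equivalent units (µg/L), driven by the external water
concentration `Cw(t)`:

    dDw/dt = kD (Cw(t) − Dw(t)),    Dw(0) = 0,

with `kD` (1/day) the dominant rate constant. `kD` is the single most
interpretable parameter: a small `kD` (≲ 1/day) means the internal state
averages exposure over days to weeks — peaks are dampened, long low
tails accumulate — while a large `kD` (≳ 20/day) means damage tracks the
exposure, so short peaks are decisive. This is the mechanism by which a
species' apparent sensitivity depends on the *shape* of an exposure
profile and not only on its magnitude, and it is what the package's
end-to-end ranking experiment demonstrates.

Two death mechanisms convert damage to survival:

- **Stochastic death (SD).** All individuals share a threshold `zw`
  (µg/L); damage above it contributes hazard at the killing rate `bw`
  (L µg⁻¹ day⁻¹): `h(t) = bw·max(0, Dw − zw) + hb`,
  `S(t) = exp(−∫₀ᵗ h)`.
- **Individual tolerance (IT).** Each individual draws a fixed threshold
  from a log-logistic distribution with median `mw` (µg/L) and shape
  `beta`; it dies at the first exceedance, so
  `S(t) = (1 − F(max_{s≤t} Dw(s))) · e^(−hb t)` with
  `F(d) = 1/(1 + (d/mw)^(−beta))`.

`hb` (1/day) is background, exposure-independent mortality. Both
variants are always calibrated and reported; the package deliberately
does not select between them.

Assumptions worth keeping in mind: organisms do not change
fundamentally during a test (hence the removal of the egg phase from
early-life-stage data), exposure is fully described by the water
concentration, and damage dynamics are first-order and time-invariant.

## Numerics

**Damage.** Exposure profiles are piecewise linear, so the damage ODE is
solved exactly on every segment
(`Dw = c0 + s·dt − s/kD + e^(−kD·dt)(D0 − c0 + s/kD)`). Interior damage
extrema satisfy `Dw = Cw` and have the closed form
`dt* = −ln(s/(kD·A))/kD`; they are inserted into the evaluation grid, so
running maxima (which IT survival depends on) are exact at grid points.
A generic adaptive Runge–Kutta integrator exists only as an independent
oracle in the tests; the analytic path agrees with it to better than
1e−6 relative error over randomized profiles (measured ~1e−8).

**SD hazard integral.** The excess hazard `max(0, Dw − zw)` is
integrated by the trapezoid rule with the `zw`-crossing times inserted
as grid points (solved on the analytic damage expression); the grid is
refined by interval halving until survival values change by < 1e−6.
Under constant exposure, both the SD integral and the IT running maximum
have closed forms; calibration detects the all-constant case and uses
them, which makes a likelihood evaluation a few vectorised array
operations.

**Likelihood.** Interval-censored multinomial death counts:
`LL = Σᵢ dᵢ ln(S(tᵢ₋₁) − S(tᵢ)) + n_K ln S(t_K)` per treatment.
Interval probabilities are floored at 1e−30 before the log; fits that
rely on the floor are counted and flagged. The conditional-binomial
simulator draws survivors at `tᵢ` as
`Binomial(survivors(tᵢ₋₁), S(tᵢ)/S(tᵢ₋₁))`, exactly the sampling model
the likelihood assumes.

**Calibration.** Search is in log10 parameter space within data-scaled
bounds: `kD ∈ [ln(20)/t_end/100, 1000]` 1/day, thresholds
`∈ [c_min⁺/1000, 2·c_max]` µg/L, `bw ∈ [1e−4, 1e4]` L µg⁻¹ day⁻¹,
`beta ∈ [0.1, 100]`, `hb ∈ [1e−6, 0.1]` 1/day. Data-scaled bounds make
an estimate pinned at a bound a diagnosis (uninformative data) rather
than a silent clip; estimates within 1% (log scale) of a bound are
flagged. The optimiser is a seeded Latin-hypercube screen (default 200
points) followed by bounded Nelder-Mead refinement from the best 10.
When the likelihood is flat in the threshold (no dose-related deaths) or
in `hb`, the estimate is snapped to the uninformative bound
(threshold high, `hb` low) so the plateau has a deterministic,
recognisable representative.

**Confidence intervals** are likelihood-ratio profiles: the 95% interval
is where the log-likelihood, re-maximised over the other parameters,
stays within χ²₁(0.95)/2 = 1.921 of the maximum. The profile is traced
by geometric outward stepping plus bisection; each inner re-optimisation
is started from both the previous profile point's optimum and the global
MLE, because a single chained warm start can strand the simplex and
collapse one side of the interval. Intervals are clipped (and flagged)
at search bounds. Measured coverage on the standard synthetic design is
92–97% per toxicity parameter over 100 replicates.

**LPx.** The LPx of a profile is the factor multiplying the whole
profile that yields x% mortality at the end of the profile window.
Background hazard is set to zero during prediction so the endpoint
measures toxicant-attributable mortality only and is independent of
test-specific control survival. Damage linearity in the exposure makes
`S_end` monotone in the factor: SD uses Brent root finding on
`log10(factor)` over [1e−6, 1e6] (relative tolerance ~1e−4, grid dense
enough to resolve the `1/kD` transient), IT uses the closed form
`LPx = (mw/Dmax₁)·(x/(100−x))^(1/beta)`. Effects are evaluated at the
fixed end of the profile window (no moving window); uncertainty is
propagated by sampling parameter sets uniformly (log10 space) from the
profile-interval box and accepting those within the 95% likelihood
region — cheap, and consistent with the frequentist calibration.

**SSD / HP5.** A log-normal (base-10) distribution is fitted by maximum
likelihood (n-denominator sigma) to one LP50 per species;
`HP5 = 10^(mu + sigma·z₀.₀₅)` is the factor at which 5% of species reach
50% mortality. A single family is used: with five species the family
choice is weakly informed, and multi-family model averaging is left as
an extension. HP5 is computed from LP50 point estimates only; LP50
uncertainty is not propagated into the SSD.

## Data preparation

Early-life-stage data pass through four steps in a fixed order:
pre-hatch observations dropped and time re-zeroed at hatch → survivor
counts capped at the previous value per replicate (erroneous "dead"
scorings; preserves the final-day total) → replicates pooled by
summation → control and solvent control pooled. Capping before pooling
matters (the operations do not commute), which the tests demonstrate on
a fixture. Control-similarity pretests are out of scope; pooling is the
data author's decision.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the study inputs, not any
real compound: constant-exposure acute tests (default: five
concentrations on a geometric ladder plus control, 40 fish, daily
observation over 4 days) simulated with the conditional-binomial
process under known parameters, and three hourly-resolved scenario
shapes idealising typical FOCUS surface-water output — a single sharp
~2-day pulse, a single peak with first-order decline (default half-life
10 days over 60 days), and a train of sharp pulses (default 4 over 30
days). The five-species panel spans `kD` from 0.25 to 100/day — the
order-of-magnitude range reported for fish — pairing slow kinetics with
a low threshold and fast kinetics with a higher threshold and killing
rate, so the panel's sensitivity ranking reverses between pulse-like
and long-tail profiles by construction.

Passing tests therefore show that the chain is self-consistent and
statistically calibrated under its own assumptions (binomial sampling,
truly constant test exposure, no inter-replicate variability, correct
model family). They do not show robustness to real-data features such
as measured-concentration drift, life-stage effects beyond the hatch
cut, overdispersion, or model misspecification — except for one
deliberate case: the panel study calibrates *both* variants to
SD-generated data, as real studies fit both variants to the same
observations without knowing the true mechanism.

## Problem sizes used in the shipped checks

The test suite runs 100 random profiles against the ODE oracle, 100
replicates per variant for interval coverage, and 10 randomized
parameter/profile cases for the LPx defining property. The acceptance
script uses 100 oracle profiles, 20 recovery replicates per variant
(reduced-screen fits: 60 Latin-hypercube points, 4 refinements), and
the full 5-species × 3-profile × 2-variant panel study with a 100-point
screen. These sizes were chosen to keep a complete desk run in minutes
while leaving the statistical assertions well-powered.

## Known limitations

- Full GUTS (separate internal-concentration and damage states),
  sublethal endpoints, and time-varying `kD` are out of scope.
- Bayesian (MCMC) calibration is not implemented; the frequentist path
  is the supported one.
- No extrapolation outside a profile's recorded window; slow-`kD`
  species can accrue damage after a short profile ends, and that
  post-window mortality is by construction not counted when the window
  ends at the last recorded node.
- `kD` values well above ~5/day are weakly identified by daily
  observations of a 4-day test (damage equilibrates between
  observations); predictions for peak-driven profiles are insensitive
  to this, but the parameter itself may sit near a bound.
- The SSD uses one distribution family and point LP50s; HP5 intervals
  are not produced.
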