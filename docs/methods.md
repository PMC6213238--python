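# Methods

This note records the models implemented in `soildeg`, their assumptions,
the defaults and the numerical choices, in the package's own words.

## Kinetic core

Organic-conditioner loss is modelled as a single first-order pool,
`dC/dt = L − kC`. Multi-pool (active/slow/passive) formulations are
deliberately out of scope: the materials of interest (peat modifiers,
acrylic hydrogels) degrade on sub-decadal time scales where one effective
pool is adequate, and every downstream design formula (characteristic
times, burial depths) assumes it.

Conventions fixed in `core_kinetics`:

* `T₀.₉₅ = 3/k` uses the factor 3 (the conventional rounding of ln 20 ≈
  2.996), so `T₀.₉₅/T₀.₅ = 3/ln2 ≈ 4.328` identically for every estimate.
* The time scale `T₀ = 1 year` in the respiration→k conversion is a fixed
  constant; the *period of biological activity* `T_b` (days per year) is
  the configurable quantity. Default 365 d for potential (optimum
  condition) rates; 200 d is the conventional choice for temperate field
  conditions and is passed explicitly where wanted.
* The canonical respiration flux is **carbon-based** (mg C kg⁻¹ h⁻¹). The
  worked conversion of instrument output (mg CO₂ kg⁻¹ h⁻¹) multiplies by
  12/44 first (`k_from_co2_respiration`). The daily loss
  `p = 24·10⁻²·U_c/C%` compounds as `ln 100 − ln(100−p)` rather than
  linearising, though for the typical p ≪ 1 %/day the two agree to <1 %.
* Exponential series fits run in natural scale by nonlinear least squares
  (`scipy.optimize.curve_fit`), matching how exponential regressions of
  mass-loss data are conventionally reported; a log-linear mode exists for
  cross-checks. The intercept y₀ is pinned to the first observation by
  default — a retained-mass series defines its own 100 % — with a co-fit
  option, since either convention is defensible for field series.
* Reported rounding (half-lives to 0.1 yr, depths to whole cm) happens
  only at the reporting layer; raw values are always retained.

## Incubation conversions

`respiration_rate` is a pure ideal-gas computation: headspace moles
`n = PV_g/RT`, of which the fraction ΔX%/100 is incubation-produced CO₂.
The vial gas volume is accepted in mL and converted internally (×10⁻⁶ m³);
all other units are SI on input. The adsorption/dissolution (degassing)
correction is a laboratory step that only alters ΔX%, so the increment is
treated as already corrected. Small negative increments (≥ −0.5 %) clamp
to zero as instrument noise; anything more negative raises a measurement
error. Validation windows (250–330 K, 0.8–1.1 bar) catch unit mistakes
(°C given as K, hPa as Pa) rather than physical impossibility, and can be
switched off.

Soil physical state follows the standard definitions: W% gravimetric,
ρ_b = m_s/V_t, and total moisture capacity `W_s = ρ_w(1/ρ_b − 1/ρ_s)` —
the pore volume filled with water, per unit solid mass. Default particle
densities: 1.6 g cm⁻³ (peat/organic), 2.65 g cm⁻³ (mineral); any other
value must be supplied explicitly and must lie in (1, 3).

The qualitative activity classification (`classify_activity`) uses a
threshold table that is the package's own opinion (very high ≥ 30, high ≥
10, moderate ≥ 3, low ≥ 1 mg CO₂ kg⁻¹ h⁻¹); the literature criteria it
mirrors are not printed in a single agreed form, so the table is fully
overridable.

## Hydrothermal response surface

`m(T) = Q10^((T−T_m)/10)` is an empirical description over 0..T_m
(default T_m = 30 °C, Q10 = 2). Above the optimum real rates fall off, so
evaluation there requires an explicit `extrapolate=True`; the forced-decay
model enables it internally (clamping at factor values ≥ 1 would bias
summer rates low, and monitoring series graze the optimum routinely).

`f(W)` is the two-exponent unimodal factor with the algebraic extremum
`W_m = a/(a+b)`, stored redundantly and checked at construction. Fits run
in (log a, log b, log u_max) to enforce positivity — the natural-scale
problem is unconstrained-positive and the log chart makes the
Levenberg–Marquardt steps scale-free. Initialisation is deterministic:
w_opt₀ from the empirical argmax, a₀ = 2, b₀ = a₀(1−w_opt₀)/w_opt₀,
u_max₀ = max observed rate. Two u_max conventions are supported:
`"normalized"` (default — u_max pinned to the empirical maximum, matching
dimensionless reported fits) and `"fit"` (co-fitted, appropriate when the
grid may miss the optimum). Data entirely on one limb of the curve leave
(a, b) unidentifiable and raise an ill-posed-fit error rather than
returning a spurious optimum.

The *standard error of approximation* `s` is the RMS residual of rates
normalised by u_max, i.e. on the 0–1 scale of the factors. Parameter
standard errors come from the Gauss–Newton covariance in log scale,
delta-method transformed; p-values are the conventional H₀: parameter = 0
t-tests of nonlinear-regression reports.

The exponential rate law `k(T) = k₀·e^(s·T)` is the degenerate-moisture
special case for always-wet materials (hydrogels contain plant-available
water by construction); its implied Q10 is e^(10s) (≈ 1.54 for the arid
reference fit k₀ = 0.2834 yr⁻¹, s = 0.0435 °C⁻¹).

## Forced decay simulation

`simulate_decay` integrates `dC/dt = −k(t)·C` with k in yr⁻¹, time in
hours, and a fixed year of 8760 h / 365 d. The default integrator is
adaptive RK45 at rtol 1e-8; an exact piecewise-constant-rate integrator on
hourly steps (k at interval midpoints) is retained as an independent
cross-check, and the two agree to ~1e-4 relative on the arid scenario.
Because k(t) does not depend on C, the loss *fraction* is provably
independent of the initial dose; tests assert it.

The bundled arid forcing is the diurnal sinusoid
`T(t) = 38.14 + 4.45·sin(2πt/23.85 + 4.18)` with t in **hours** — the
period (23.85 ≈ 24) identifies the cycle as diurnal, and the standard
reporting horizon of 580 h is consistent with that reading. For sinusoidal
T and exponential k(T) the cycle-averaged rate has the closed form
`k₀·e^(s·T₀)·I₀(s·a)` (modified Bessel function of order zero), used as an
analytic oracle: the arid scenario gives k_eff ≈ 1.503 yr⁻¹, hence ~9.5 %
loss in 580 h and ~31 % in three months (2160 h = 90 d; with 92 d the
figure rises by ≈ 1 point — horizon and phase are exposed explicitly so
either convention can be run).

Tabulated monitoring series are interpolated with a shape-preserving
monotone cubic (PCHIP) by default, so the forcing never overshoots the
data range; linear interpolation is the alternative. Extrapolation beyond
the tabulated span is refused. No temperate-zone monitoring series is
bundled as data; `synthetic_data.moscow_like_forcing()` provides a clearly
synthetic annual sinusoid (mean 6 °C, amplitude 14 °C, winter minimum at
t = 0) for temperate-scenario testing. Passing tests against it show the
pipeline's correctness, not agreement with any observed urban climate.

## Depth screening and nomographs

Biological activity vs depth is fitted as `U_m(h) = U₀ + a·e^(−bh)` with
U₀ constrained ≥ 0. Characteristic depths mirror the kinetic
characteristic times: `H₀.₅ = ln2/b`, `H₀.₉₅ = 3/b`; over the typical
mineral-soil range 0.1 ≤ b ≤ 1 cm⁻¹ they span 1–7 cm and 3–30 cm.

The burial-depth rule `H = ln(n)/b` attenuates the *surface-excess*
activity and ignores the floor U₀ — with a nonzero floor an n-fold
reduction of total activity may be unattainable at any depth. A
floor-aware variant solving `U₀ + a·e^(−bH) = (U₀+a)/n` is provided
(`burial_depth(n, profile=...)`) and raises when the target undercuts the
floor. Nomograph tables are computed analytically cell by cell, so
`exp(b·H) = n` holds exactly everywhere; the default reduction-factor list
(2, 3, 4, 6, 8, 16, 32) follows the curves customarily drawn and is a
package choice. In active-layer mode the attenuation is recovered from the
biogenic-horizon thickness as b = 3/H₀.₉₅; note the analytic depth for
(H₀.₉₅ = 20 cm, n = 2) is 4.62 cm, whereas graphical nomograph readings of
this case are sometimes quoted as ≈ 6 cm — the package always computes
analytically.

## Water retention

The van Genuchten curve in the Mualem-constrained form (m = 1 − 1/n),
water content in mass-%, pressure in kPa over the centrifugation range
0–1000. Fits are bounded (0 ≤ θ_r < θ_s ≤ 100, α > 0, 1 < n ≤ 15),
initialised with θ_s from the lowest-pressure point, and refuse flat
curves (< 0.5 % content range) as ill-posed. Field capacity is read from
the fitted curve at a *configurable* drainage potential; the package
default of 33 kPa is a common agronomic convention and explicitly an
opinion, not a measured criterion — secondary-maximum-of-capillary-
capacity style criteria can be emulated by supplying the corresponding
potential.

## Synthetic data

Generators in `synthetic_data` produce every input class with embedded
ground truth (a `# truth: {json}` header line above the CSV header) and
are bit-reproducible per seed (`numpy.random.default_rng`). Noise is
additive Gaussian — replicate errors in incubation work are reported as
symmetric ± values — with a relative-noise option for heteroscedastic
cases. Default truths and noise levels mirror the study conditions the
package targets: moisture exponents (4.84, 2.35) with optimum ≈ 0.67 W/Ws
and 5 %-of-maximum rate noise; a 0.77 yr⁻¹ two-year monthly decay series
with 2-percent-point noise; a depth profile (U₀ = 0.5, a = 20, b = 0.3
cm⁻¹) with 5 % relative noise; a sandy-substrate retention curve
(θ_r = 3 %, θ_s = 40 %, α = 0.1 kPa⁻¹, n = 1.8) with 0.5-point noise.
Seasonally modulated decay series scale k by the Q10 factor of the
synthetic temperate cycle, renormalised to keep the annual-mean constant —
winter months then lose less than summer months by construction.

What the generators do **not** emulate: serially correlated measurement
drift, heteroscedasticity tied to instrument range, replicate structure,
or the spatial covariance of field profiles. Recovery tests on these data
therefore demonstrate estimator correctness and stated-noise robustness,
not performance on any particular field campaign.

## Problem sizes and determinism

All computations are desk-scale. The test suite's Monte-Carlo checks use
100–200 seeds per scenario (each fit is milliseconds); the ODE scenarios
integrate ≤ 200 diurnal cycles. The acceptance script evaluates
trajectories on 2001 nodes and finishes in seconds. CLI reports serialise
with sorted keys, so identical invocations are byte-identical; the only
randomness anywhere is the explicit integer seed.

## Known limitations

* One pool, first order: no substrate feedback, no priming, no microbial
  dynamics (Monod-type models are out of scope by design).
* Forcing is prescribed, never simulated — no soil heat or moisture
  transport.
* The depth model is empirical; no reactive transport of oxygen or
  substrate.
* `m(T)` above the optimum is extrapolation; the forced model uses it
  knowingly for brief excursions.
* Retention fitting stops at the curve; no hydraulic conductivity
  prediction.
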