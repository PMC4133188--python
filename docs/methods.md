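# Methods

## Scope and observables

The measurement principle is differential: the same pen, at the same spring
state (same delivered volume), injects slower into tissue than into air, and
the flow deficit prices the tissue counter pressure through the device's
pressure balance.  The raw observable is a *click train* — timestamps of the
pen's per-10 µL clicks — from which interval flow rates
`Q_i = V_click / Δt_i` follow directly.  Flow is assigned to interval
midpoints in time, and to the delivered-volume midpoint
`V_mid,i = (i + 3/2)·V_click` (the first click marks the first completed
increment).  Air/tissue pairing is done on the volume coordinate, not time,
because the spring force depends only on piston position.

The last intervals of a recording are excluded (default: 2): the pen
deliberately drops its spring force at the end of an injection, producing a
flow drop unrelated to the spring curve.  A change-point helper flags a
suggested truncation (flow drop > 30% between consecutive trailing
intervals) but never applies it silently.

## Click detection

Clicks are impulsive and sparse (~10–20 Hz), so detection is deliberately
simple: a moving-RMS envelope (1 ms window) is thresholded at
`threshold_sd` (default 6) robust standard deviations above the envelope's
noise floor, where floor and spread are the envelope median and scaled MAD —
statistics the sparse clicks barely perturb.  Each suprathreshold excursion
reports its envelope peak; a refractory period (default 20 ms, well below
the ≥ 50 ms inter-click spacing) suppresses ringing doubles.  On synthetic
audio at 20 dB SNR all clicks are recovered to well under 1 ms.  Audio I/O
is mono WAV (PCM 16/24/32-bit or float, any rate ≥ 8 kHz) via
`scipy.io.wavfile`; multi-channel input falls back to the first channel with
a warning.  No denoising beyond envelope thresholding is attempted.

## Device balance

With syringe radius `r_s`, needle radius `r_n` and length `L_n`, the outlet
pressure is `p₂ = F/(π r_s²) − Δp_needle(Q)` with

    Δp_needle(Q) = 8 μ L_n Q / (π r_n⁴) + α ρ Q² / (2 π² r_n⁴).

The second term models the kinetic-energy/entry cost of accelerating the
fluid into the needle; `α = 2` is the kinetic-energy flux coefficient of a
parabolic profile and is configurable, since the exact entry-length
correction depends on geometry details the balance cannot resolve.  At
bolus rates (100–150 µL/s through a 31G needle) the kinetic term is the same
order as the viscous term, so it cannot be dropped.  The syringe-bore
viscous drop is smaller than the needle drop by roughly `(r_n/r_s)⁴` and is
neglected; a diagnostic ratio is exposed and asserted ≫ 1 in the tests.
Piston friction is absorbed into the calibrated `F(V)` under the assumption
that it does not depend on flow rate.  All pressures are absolute, with
`p_ref = 101325 Pa` by default.

Spring calibration pools every air reference (typically one before and one
after the tissue injection) onto a shared 10 µL volume grid by averaging,
then projects onto the non-increasing cone (isotonic regression): a torsion
spring only untwists, and the projection also absorbs single-interval
outliers.  Defaults: `r_s = 4.75 mm` (3 mL pen cartridge), `r_n = 66.5 µm`,
`L_n = 6 mm` (6 mm 31G needle), water viscosity and density for the drug.

## Poro-elastic pressure model

Around the needle tip the subcutis is treated as homogeneous, isotropic and
spherically symmetric.  With Darcy flow `u = −(k/μ)∂r p` and the linear
constitutive law `φ = φ₀ + (p − p₀)/K`, mass continuity of the
incompressible injectate gives

    ∂p/∂t = (K k / μ) (1/r²) ∂r ( r² φ ∂r p ),

on `r ∈ [r_inner, r_outer]`, with the full flow rate crossing the inner
sphere (`∂r p = −Qμ/(4π r_inner² k φ)` at `r_inner`, taken equal to the
needle radius) and `p = p₀` at the far boundary.  Tissue advection and
relative volume changes are neglected.  The porosity weight inside the
divergence is the pressure-dependent `φ` (consistent with the flux boundary
condition); a linearised variant with `φ₀` as mobility weight is available
via `linearized=True` and reduces to linear diffusion with
`D = K k φ₀/μ`, whose steady state is the closed form
`p(r) = p₀ + Qμ/(4π k φ₀ r)` used as an analytic oracle.

Parameters and defaults: permeability `k` (m², adipose-tissue scale
1e-11–1e-10), bulk modulus `K` (Pa, ~1e5), background porosity `φ₀ = 0.01`
(small), undisturbed pressure `p₀ = 101325 Pa` — the far field is assumed
atmospheric; the true subcutis resting pressure may sit slightly below, and
`p₀` is exposed in config for that reason.

### Numerics

Conservative finite volumes on a logarithmic radial grid (default 200
cells, `r_outer = 50 mm ≥ 100·r_inner`), faces at geometric progression and
cell centers at face geometric means.  Time integration is LSODA with a
banded Jacobian (`rtol = 1e-6`, pressure `atol = 1 mPa`).  Cumulative
injected volume and far-field outflux ride along as extra ODE states, so
the global mass balance `∫(φ−φ₀)dV + outflux − injected` is a genuine
solver diagnostic; it closes to ~1e-13 relative on standard runs and is
asserted < 1% everywhere.  The tip pressure is extrapolated from the first
cell center to `r_inner` through the flux boundary condition, solving the
small quadratic the nonlinear `φ` introduces.

The linear law can push `φ` above unity near the needle at high pressure,
where it is no longer meaningful; the mobility is clamped to
`φ ∈ [1e-6, 1]` and clamp events are counted in the diagnostics.  A
porosity that reaches zero (suction beyond the law's validity) raises a
stiffness-failure error.  `Q(t)` supplied as a flow series is interpolated
linearly between interval midpoints with constant extrapolation at the
edges.  Halving the grid spacing changes the tip pressure by < 0.5%
(tested).

The depot radius (largest `r` where the over-pressure still reaches a given
fraction of its needle-surface value) is located by interpolating
`log(p − p₀)` against `log r`, which is exact for the quasi-steady `1/r`
profile.

## Counter pressure and cohort summary

Per tissue interval, `p₂(V_mid) = F(V_mid)/(π r_s²) − Δp_needle(Q_tissue)`
and the counter pressure is `p₂ − p_ref`.  Identical air and tissue flow
series give exactly zero by construction.  The per-subject summary is the
unweighted mean over retained intervals (equal-volume intervals make this
volume-weighted automatically).  Cohort statistics are a notched box:
type-7 linear-interpolation quartiles (stated because box edges depend on
the convention), whiskers at the extreme included values, and the
`median ± 1.57·IQR/√n` notch as an approximate 95% CI for the median.
Subjects whose mean counter pressure falls below a detection floor
(default 10 mbar ≈ the ~2% flow-measurement accuracy propagated through the
device balance) are excluded and counted: for them the method only bounds
the tissue resistance from above.

## Inverse fit

`(k, K)` minimise the sum of squared differences between the device-derived
`p₂(t_i)` and the model tip pressure driven by the measured tissue flow,
over `log₁₀ k ∈ [−14, −8]` and `log₁₀ K ∈ [3, 8]` with a bounded
Nelder-Mead simplex from `(1e-11 m², 1e5 Pa)`.  Log-space absorbs the
multi-decade prior uncertainty; residual weighting is uniform.  `φ₀` and
`p₀` are fixed during the fit (an option frees `φ₀`).  The search runs the
PDE at `rtol = 1e-5` on a 120-cell grid (tip pressure is grid-converged far
below measurement noise there); the final SSE is re-evaluated at
`rtol = 1e-6`.  Solver failures at trial parameters are mapped to a large
penalty rather than a crash, and near-bound optima set `bounds_hit` flags —
a zero counter-pressure series, for instance, is unidentifiable and pushes
`k` to its upper bound.

### Identifiability under timing jitter — a known limitation

The quasi-steady tip over-pressure is ≈ `sqrt(2K·Qμ/(4πk r_inner))`: it
constrains the *ratio* `K/k` strongly but the common scale
`(k, K) → (c·k, c·K)` only weakly (through the slow diffusive transient and
the small `φ₀` term).  On noise-free synthetic subjects the fit recovers
both parameters to < 1%.  Under per-click timing jitter two effects degrade
recovery along the soft direction: (i) jitter of `σ_t` on intervals `Δt`
makes flow noise `δQ/Q ≈ √2 σ_t/Δt`, which the needle drop amplifies into
pressure noise `Δp′(Q)·δQ` (several kPa at 2 ms jitter) against which the
valley is shallow; and (ii) because the model is driven by the *same*
measured (noisy) flow, and its instantaneous tip response `∂p_tip/∂Q`
shrinks as `c` decreases, the expected SSE is systematically tilted toward
small `c` — an errors-in-variables attenuation intrinsic to this estimator.
Replicate simulation studies at the default conditions (240 µL dose,
`k = 5e-11 m²`, `K = 1e5 Pa`) give median absolute relative errors of ≈ 35%
at 1 ms jitter and ≈ 54% at 2 ms for both parameters, with the ratio `K/k`
still recovered to a few percent.  Cohort *medians* of the fitted
parameters remain within the generating ranges, and order-of-magnitude
statements about `k` and `K` are robust; individual-subject values under
realistic jitter are not precise beyond a factor ~2–4 along the soft
direction, and should be read together with the well-determined `K/k`.

## Synthetic data generator

The generator exists because no recordings of this kind are deposited
anywhere; it defines the conditions under which the pipeline is validated.
It integrates the *fully coupled* device–tissue system: delivered volume
`V` is the first ODE state, the instantaneous flow solves the scalar
balance `F(V)/(π r_s²) = p_tip(Q) + Δp_needle(Q)` inside every
right-hand-side evaluation (bracketed Brent iteration), and the tissue
field advances with the same conservative finite-volume scheme.  Operator
splitting at a fixed step was rejected: the near-needle cells are ~10³
times smaller than the volume injected per millisecond, so any
frozen-mobility split step overshoots to a wrong quasi-steady state.
Placing `V` first keeps the Jacobian tridiagonal.  Click times are roots of
`V(t) = m·V_click` on the dense ODE output; independent Gaussian jitter
(default sd 2 ms) models microphone/detection error.  A stalled injection
(spring unable to overcome tissue pressure) returns a flagged partial dose.

Cohorts draw `k` and `K` log-uniformly (defaults `[1e-11, 1e-10] m²`,
`[3e4, 3e5] Pa`), doses uniformly in 180–480 µL rounded to the click
volume, and one pen per subject with two air references (before/after) plus
one tissue injection, mirroring the clinical pairing.  Springs are linear
in delivered volume and parameterised by their air-flow envelope — start
flow ~U[140, 160] µL/s decelerating to ~U[70, 90] µL/s over the dose — with
the forces derived from the device balance; specifying flows rather than
forces pins the synthetic profiles to the decelerating shape real pens
show regardless of the configured geometry.  The pen's deliberate
end-of-injection force drop is not simulated; an option appends two
artificially slow trailing clicks to exercise tail truncation.  WAV
rendering (damped 4 kHz sinusoids in Gaussian noise) provides just enough
acoustic realism to exercise the detector.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: physiological heterogeneity (layered
dermis/subcutis, lipohypertrophy, anisotropy), backflow along the needle
channel, drug absorption, acoustic room effects, or nonlinear/plastic
tissue response beyond the clamped linear law.  Synthetic spring curves and
doses are plausible stand-ins for unpublished patient-level values and are
flagged as synthetic in all outputs.

## Problem sizes used in the shipped checks

The acceptance script solves the representative depot-localization case on
200 log-spaced cells over 2 s of injection; the replicate recovery studies
in the test suite use 10 jittered replicates of one subject and a 5-subject
cohort with 120-cell fitting grids.  These sizes were chosen so the full
validation remains comfortable on a single CPU while staying in the regime
where the solver's grid-convergence checks hold.
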