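# Methods

This note documents the models, estimators and numerical choices behind
`swarmstate`, and what the synthetic-data tests do and do not establish
about real swarm recordings.

## Units and conventions

Millimetres and seconds throughout; the z axis is vertical (gravity).
Midge mass is taken constant and set to 1, so energies, pressure and
temperature are per unit mass; the effective Boltzmann constant is
likewise absorbed (k_B* ≡ 1), since the system has no intrinsically
preferred temperature scale. Frame clocks default to 100 Hz.

## Trajectory processing

Velocities and accelerations are obtained by differentiating positions in
time: central differences at interior frames and second-order one-sided
differences at track endpoints (`numpy.gradient`, `edge_order=2`). This
scheme is exact on constant-acceleration trajectories, including at the
endpoints, which makes the integrate-back check (cumulative trapezoid of
velocity reproducing positions to 1e-6 mm on quadratic tracks) hold
without special-casing. An optional centred boxcar can pre-smooth
positions; the default applies none, because the synthetic data carry no
measurement noise and the pressure estimator already avoids
double-differentiated accelerations (see below).

Tracks are split, never interpolated, across frame gaps — no gap-filling
procedure is assumed — and tracks shorter than 3 frames are dropped with
a warning since they cannot be differentiated.

The flight filter removes non-flying midges time step by time step: a
midge is discarded wherever the centred moving average (default 100
frames, truncated at track ends) of its speed falls below 60 mm/s.
Centred alignment is chosen to avoid phase lag; removal is instantaneous,
so filtered midges do not count toward N at those frames. Removals can
split tracks into segments. The filter is idempotent on data whose slow
episodes are coherent (as in real and simulated flight); a pathological
speed profile alternating spikes and gaps could in principle yield
further removals on a second pass, because truncated windows are
recomputed within each segment.

## State variables

Per frame: N is the number of flying midges; V the convex-hull volume of
their positions (Qhull), flagged undefined for N < 4 or degenerate
configurations and skipped by all downstream fits; the centre of mass is
the arithmetic mean position.

The emergent spring constant is estimated per frame as the swarm average
⟨−**a**ᵢ·r̂ᵢ/rᵢ⟩ with r̂ᵢ the outward unit vector from the centre of mass
to midge i, so that a pure restoring acceleration −k rᵢ yields +k.
Midges within 1e-6 mm of the centre are excluded (division by rᵢ; a
measure-zero case). These per-frame estimates, averaged per swarm size,
are fitted in log-log space to k(N) = a·N^b; the pressure then uses the
*fitted* law evaluated at the instantaneous N rather than the per-frame
estimate, which suppresses the noise amplification inherent in
double-differentiated accelerations. Both quantities are stored
(`k`, `k_inst`) so the two routes can be compared.

The virial pressure is P = (1/3NV)·Σ(vᵢ² − ½k rᵢ²); it may be negative on
potential-dominated frames.

σₓ and σᵥ are per-frame means of the three component rms values
(velocities about zero; positions about the per-frame centre of mass),
averaged over a centred sliding window of 1 s (100 frames) by default.
The horizon is a configuration parameter (`sigma_window`): a window short
enough to track perturbation transients but long enough to tame N-small
rms noise. Entropy and temperature then follow from their closed forms

    S = (3N/ln 2)·ln(2πe σₓ σᵥ)   [bits]
    k_B*T = (3/2) σᵥ² N (2^{2/3N} − 1)  →  σᵥ² ln 2  (N → ∞)

with S, T defined only where N ≥ 1 and both σ's are positive. The
Gaussian closed form for S is verified in the tests against direct
numerical integration of the factorized joint PDF across four decades
of σ. The temperature reaches its intensive limit within 2% for N ≥ 20.

## Equation of state

P is modelled as c₄·V^c₁·(k_B*T)^c₂·N^c₃, the leading term of a
virial-like expansion. Before fitting, all four variables are normalized
by their rms over jointly-defined frames; the factors are absorbed into
c₄ and leave the exponents unchanged (verified by a unit-rescaling
invariance test). The nonlinear least-squares fit starts from the neutral
guess (−1, 1, 1, 1) — deliberately not any known answer — and uses an
analytic Jacobian with parameter/cost tolerances of 1e-12 (up to 10⁴
evaluations); non-convergence raises an error carrying the last iterate.

Negative-P frames are retained in the nonlinear fit (the positive model
surface can only approach them from above, but they constrain the fit);
the independent cross-check — ordinary linear regression of log P on
(log V, log T, log N) — necessarily uses only P > 0 frames.

Exponent standard errors use a heteroscedasticity-robust (sandwich)
covariance: the dominant noise is multiplicative, so residual variance
scales with P and the naive s²(JᵀJ)⁻¹ form would understate the
uncertainties severalfold (coverage of ±2 SE is verified at ≥ 90% over
repeated synthetic ensembles). Temporal correlation between frames is
handled by a subsampling stride (default 10 frames); the results carry
both the strided SE and a naive all-frames rescaling for comparison.

## Equipartition

Frames are grouped by instantaneous N; the mean E/(k_B*T) per group, with
its standard error, is regressed on N through the origin (E vanishes with
the swarm) by inverse-variance weighted least squares, falling back to
equal weights when bin SEs are undefined (single-frame bins, exact
synthetic data). The effective degrees of freedom per midge are twice the
slope; the ln 2-discounted count (2·slope·ln 2) is reported alongside.
For a virial-balanced Gaussian swarm the exact group mean is
2(2N−1)/(2N) / (2^{2/3N} − 1), giving a large-N slope of 3/ln 2 ≈ 4.33 —
within 4% of 9/2, hence 9 d.o.f. after rounding. An anisotropy report
decomposes the energy into 3 kinetic + 3 potential per-axis modes.

## Perturbation cycles

The perturbation protocol is a periodic four-state light/sound schedule
(default period 40 s, switches every 10 s). Frames are assigned the phase
(t − start) mod period and binned (default 400 bins, 0.1 s at the default
period); per-bin means of P, V, T, N form the phase-averaged cycle.
Smoothing is a circular (wrap-around) moving average — phase is periodic,
so no edge convention is needed — of 3.5 s by default, weighted by
per-bin frame counts so empty bins (possible after the flight filter)
acquire values from their populated neighbours; with uniform counts it
reduces to a plain boxcar and conserves the cycle mean exactly. The P–V
loop orders bins by phase, closes by wrap-around, interpolates any empty
bins circularly (flagging them), and reports the signed shoelace area.

Cycle reconstruction evaluates the EOS (fitted on *unperturbed* data) per
frame of the perturbed series, phase-averages it with the identical
schedule, bin count and smoothing, and reports bin-wise correlation and
normalized rms error, overall and per protocol state.

## Synthetic swarms

The generator integrates, per midge and per component, the damped
harmonic Langevin equation

    dv = (−k x − γ v) dt + √(2γ) σᵥ dW,    dx = v dt

with Euler–Maruyama at dt = 0.01 s, guarded by γ·dt ≤ 0.1 and k·dt² ≤ 0.1;
an exact Gaussian-transition mode (matrix exponential plus stationary-
covariance increment) is available as a cross-check oracle and agrees
with the default integrator to within Monte-Carlo error. Initial
conditions are drawn from the stationary distribution, so recordings are
stationary from frame 0; positions are offset to a fixed marker location
(1 m above origin by default) and optional Gaussian jitter emulates
measurement noise. Everything is reproducible from a single seed;
ensemble members draw independent child seeds deterministically.

This process is the *minimal* one with the statistical structure the
analysis assumes — harmonic binding, Gaussian and isotropic marginals,
virial balance (k σₓ² = σᵥ² exactly in stationarity), slow N variation (N
is constant within a recording and varies across an ensemble). Default
conditions mirror the laboratory regime: N of 10–100, σᵥ = 200 mm/s,
γ = 2 s⁻¹ (velocity correlation ~0.5 s), spring law 25·N^(−1/2) s⁻²
(decimetre-scale swarms), 100 Hz sampling. A `kinetic_boost` β scales the
dynamical spring to β²k so that analyses using the nominal law see a
controlled kinetic/potential imbalance, for stress tests.

Perturbed runs drive the σᵥ target through per-state multipliers with a
startle transient at every switch — a jump by a configurable amplitude
factor (default 1.5) relaxing exponentially (default τ = 2 s) — and the
spring through per-state multipliers. No quantitative startle magnitude
is established for real swarms; these defaults produce loop-shaped P–V
cycles qualitatively, not quantitatively.

What passing tests show — and do not. The generator reproduces the
moment structure of real swarms, not their behaviour: there are no
pairwise interactions, no ground-induced vertical asymmetry, no
measurement noise or tracking gaps unless injected. Parameter-recovery
results (EOS exponents to ±0.05 at 5% noise and n = 5000; equipartition
slope to ±10%; spring-law exponents to ±0.1) therefore validate the
estimators and the pipeline plumbing, not the biological claims; analysis
of the laboratory dataset requires the published trajectory archive.

## Problem sizes

The validation suite uses 10⁴-frame recordings (100 s at 100 Hz) with
N up to 100, ten-member ensembles for the equipartition fit, 5000-sample
ensembles for EOS recovery, and ten-period perturbed runs for the cycle
analysis — sizes at which every Monte-Carlo tolerance above is met with
a comfortable margin while the whole suite runs in about a minute.
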