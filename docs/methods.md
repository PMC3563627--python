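# Methods

This note documents the model, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Physical model

The circulation between heart and hand is a graph of tapered vessel
segments. Each segment is divided into 1D elements no longer than 5 cm.
For an element of length `l` with linearly varying radius `r(x)`, wall
thickness `h(x)` and Young's modulus `E`, the linearized 1D mass and
momentum equations with a Poiseuille friction closure and a thin-wall
linear-elastic tube law reduce to a transmission-line cell:

* viscous resistance `R = ∫ 8μ/(πr⁴) dx` (closed form for a linear taper,
  so a chain of elements reproduces the Poiseuille drop of the whole
  tapered segment exactly);
* blood inertance `L = ρ ∫ dx/A`;
* wall compliance `C = ∫ dA/dp dx` with `dA/dp = 2πr³/(Eh)` (Laplace-law
  linearization), lumped half to each end node.

The continuum limit of this ladder propagates small pulses at the
Moens–Korteweg speed `c = √(Eh/(2ρr))`; the spatial discretization error
in wave speed is second order in (element length / wavelength). The
solver's verification suite checks the Poiseuille drop to 1% and the wave
speed to 5% against these closed forms.

Blood is Newtonian with ρ = 1050 kg/m³ and μ = 3.5 mPa·s. A
velocity-profile hook exists only through the friction closure; the
default is the parabolic (Poiseuille) profile.

### Boundary conditions and lumped elements

* **Inflow**: a characteristic aortic waveform (raised-sine systole over a
  low diastolic plateau, systolic fraction 0.35, diastolic level 0.2 of
  the shape) scaled to a 5100 ml/min average; only its mean is treated as
  normative, the shape is a package choice.
* **Arterial ends**: three-element windkessels. `Z = ρc/A` from the
  terminal radius (Moens–Korteweg `c`), `R = (p̄ − p_out)/q̄ − Z` floored
  at zero, `C = τ/R` with a peripheral time constant τ = 1.5 s. The
  outlet pressure of every terminal, and the prescribed pressure of the
  venous outlet, is 10 mmHg. The Z/R split and τ are documented package
  constants; only `(Z + R)` is identified by the mean-flow data.
* **Baroreflex**: after virtual surgery the cardiac output is rescaled
  (amplitude only, shape and period preserved) by a secant iteration until
  the mean aortic-arch pressure is within 5% (configurable) of the
  preoperative value. Heart-rate adaptation is not modeled.
* **Anastomosis**: lumped loss `Δp = ρ/2 · q|q| · [Cv(1 − cosθ)/A_v² +
  Ca/A_a²]` with Cv = 1.0, Ca = 0.3, plus a small inertance (1 cm
  effective length). The coefficients are packaged constants; the tested
  contract is zero drop at zero flow, superlinear growth in flow,
  monotonicity in angle, and anti-monotonicity in each area. Angles
  default to 45° (lower arm) and 60° (upper arm).
* **Stenosis**: `Δp = Kv μ/(A₀D₀) q + Kt ρ/(2A₀²)(A₀/A_s − 1)² q|q| +
  Ku ρL_s/A₀ dq/dt` (+ a constant offset term, default 0), with
  `Kv = 32 (L_s/D₀)(A₀/A_s)²`, Kt = 1.52, Ku = 1.2. This Kv makes the
  healthy limit `A_s = A₀` collapse exactly onto the straight-tube viscous
  drop, which is the tested degenerate contract.

### Time integration

The assembled differential-algebraic system in (node pressures, element
flows, windkessel states) is integrated by backward Euler. The nonlinear
loss coefficients are evaluated semi-implicitly from the previous time
level (one Picard sweep per step), which keeps every step a single linear
solve and is unconditionally stable. Cycles are repeated until the
cycle-to-cycle change of the node mean pressures falls below 0.5%
(relative); non-convergence raises rather than returning silently. The
initial state is the steady (DC) solution of the same network, which a
Picard iteration solves directly; Monte-Carlo sweeps warm-start each
sample from the nominal converged state and cardiac output.

Default time step: 1 ms. The test suite and the Monte-Carlo sweeps use
5 ms with a 1 s cardiac period (200 steps/cycle), at which halving the
step changes the predicted mean arm inflow by well under 1% (tested).
The acceptance script uses 2.5 ms.

## Generic geometry

The generic heart-to-hand geometry (segment connectivity, lengths, default
radii, wall thickness h = 10% of the local radius, per-class Young's
moduli, station table) is a versioned set of packaged constants chosen to
be anatomically plausible for an adult arm; it is model input, **not**
clinical truth. The 24-location vessel-mapping protocol is represented by
a configurable station table (10 arterial, 14 venous) whose stations sit
at segment boundaries. The in-/outflow-tract stations varied in the
uncertainty analysis number 13 (lower arm) to 8–10 (upper arm), which
with the global diameter factor gives 9–15 uncertain parameters depending
on configuration.

Preoperative networks contain the arterial tree and its terminals only:
with windkessels draining at the venous outlet pressure, the veins carry
no flow before surgery and would only disconnect the graph. The
postoperative network adds the configured venous chain and exactly one
anastomosis. The distal artery remains connected across the anastomosis
node (side-to-end physiology); an end-to-side variant with ligated distal
artery is not asserted as the clinical reference, merely not modeled.

## Personalization

Arterial radius profiles (1 mm sampling) are cleaned by flagging samples
whose deviation from an 11-sample running median exceeds 3.5 robust
standard deviations (1.4826·MAD), a deterministic stand-in for visual
verification of segmentations. The radial artery gets an ordinary
least-squares linear taper; the subclavian–axillary–brachial chain gets a
continuous three-phase piecewise-linear fit (hinge basis, so continuity at
the transition points is enforced by construction) with the first-segment
slope forced to zero, because the short subclavian run does not support a
stable slope estimate. The transition points are found by exhaustive
search over observed sample positions (vectorized through suffix-sum
normal equations; an independent per-pair least-squares search is the test
oracle). Veins use the area-equivalent radius `√(major·minor)/2` of the
ultrasound ellipse.

Doppler mean flows are `0.5 or 1.0 × v̄_max × A`, always a range. For
windkessel estimation a single value is needed; the package uses the
midpoint of the range by default (configurable to the parabolic or flat
scenario; scenarios are never mixed across terminals). The distributed
(muscle) flow is the arm inflow minus radial and ulnar outflows, clipped
at zero with a warning. The rest-of-body terminal is set so that the
reference cardiac output (5100 ml/min) reproduces the measured mean
pressure preoperatively, which makes the baroreflex loop self-consistent.

## Uncertainty analysis

Uniform distributions, interpreted as nominal·(1 ± X/100) (half-width
X%): ±10% on arterial station diameters, ±30% on venous, ±10% on the
global diameter factor scaling non-measured segments, and per stenosis
±2 cm on length (floored at 0.5 cm, so the support may be asymmetric at
the floor), ±20% on healthy and diseased areas (diseased clipped to the
healthy area when independent sampling would invert the narrowing).
Latin-hypercube sampling draws `1000 × k` rows by default (one sample per
equal-probability stratum per dimension); quartiles use the
linear-interpolation empirical estimator; failed samples are excluded, not
imputed, and counted. Station diameters are sampled independently along a
vessel; no longitudinal correlation is imposed. Non-varied parameters
stay at their personalized/nominal values.

A `steady` Monte-Carlo mode propagates samples through the DC limit of
the same network (Picard-iterated nonlinear resistive solve). It is a
fast surrogate whose mean flows differ from the pulsatile cycle-means only
through the pulsatility correction of the quadratic losses (a few
percent); the packaged acceptance checks run the pulsatile mode, and the
cheap mode is used for high-replicate property tests.

## Synthetic patients

The generator emulates the study's acquisition outputs, not MR physics:
per-station true radii are lognormal perturbations (σ = 5% by default) of
the generic geometry with a flat subclavian–axillary run (so the upper
chain truth is exactly three-phase); profiles add multiplicative Gaussian
noise (σ = 5%) and 2–4× outlier spikes at a 2% rate; cross-sections are
anti-aliased bright disks (0.78 mm pixels) whose half-maximum crossing
sits at the true radius; Doppler traces invert the mean-flow formula for
a chosen true velocity profile (parabolic by default, so the true flow
sits on the low bound of the measured range). Configurable systematic
diameter biases reproduce the reported MRA-vs-US differences (arterial
≈ +9%, venous ≈ +38%); the pipeline keeps veins ultrasound-based, and a
directional test shows that feeding the biased venous diameters in shifts
the prediction upward. Ground-truth postoperative flow is defined by
simulating the true network (model-consistent truth): no analytic truth
exists for this quantity.

Three canonical fixtures mirror the case archetypes: `clean`,
`mild` (25% narrowing over 5 cm) and `severe` (75% stenosis over 3.5 cm
in the arterial inflow tract), all lower-arm radiocephalic.

What passing tests show: the pipeline recovers model-consistent truths
under its own noise model, intervals behave monotonically under stenosis
severity, and the machinery is internally consistent. What they do not
show: agreement with clinical measurements, real modality artifacts
(parallel vessels, field inhomogeneity), vascular adaptation after
surgery, or anatomical variants.

## Problem sizes and runtime choices

The packaged lower-arm network has ~40 elements (≈100 unknowns). The
test suite runs reduced-replicate Monte-Carlo (50 samples/parameter,
pulsatile mode, 5 ms step) on the three fixtures; high-replicate property
checks (20-replicate end-to-end recovery, interval convergence) use the
steady mode with 10–50 samples/parameter. These sizes are package
defaults for the shipped experiments; the full 1000/parameter budget is
the library default for analyses.

## Known limitations

* Linearized tube law (no collapse, no pressure-dependent stiffness) and
  Poiseuille friction (no Womersley profile correction by default).
* Baroreflex rescales stroke volume only; no heart-rate or autoregulatory
  response.
* Anastomosis loss coefficients are plausible constants, not fitted to
  3D simulations or in-vitro data.
* The generic geometry is a single adult-arm archetype; high bifurcations,
  accessory veins and PTFE grafts are out of scope.
* Preoperative veins are not modeled (no venous flow preoperatively by
  construction).
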