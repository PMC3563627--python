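# vaflow

Patient-specific prediction of vascular-access (VA) surgery outcome.

Hemodialysis requires a surgically created artery–vein connection (an
arteriovenous fistula) in the arm. Whether a planned fistula will carry
enough flow to mature — without stealing so much that it causes cardiac
overload or hand ischemia — depends on the patient's vascular geometry.
`vaflow` implements a planning analysis for this decision: a 1D pulse-wave
propagation model of the heart-to-hand circulation, personalized from
vessel radius profiles (angiography-like centerline data) and ultrasound
measurements, that predicts the direct postoperative arm inflow together
with a Monte-Carlo uncertainty interval reflecting the geometric
measurement uncertainty. It is aimed at researchers in computational
hemodynamics and at anyone building or evaluating model-assisted VA
planning workflows.

## Model

* **1D network.** Every vessel segment between heart and hand is divided
  into short (≤ 5 cm) elements. The linearized 1D mass/momentum balances
  with Poiseuille friction and a thin-wall elastic tube law reduce each
  element to a resistance–inertance–compliance cell:
  `R = ∫ 8μ/(πr⁴) dx`, `L = ρ∫dx/A`, `C = ∫ 2πr³/(Eh) dx`, which
  propagates pulses at the Moens–Korteweg speed `c = √(Eh/(2ρr))`.
* **Boundary conditions.** A characteristic aortic inflow waveform with a
  5100 ml/min average; three-element windkessels (Z, R‖C) at the arterial
  ends; a prescribed 10 mmHg pressure at the venous outlet. Postoperative
  cardiac output is iteratively rescaled until the mean aortic-arch
  pressure returns to within 5% of the preoperative value (baroreflex).
* **Surgical elements.** The anastomosis is a lumped junction whose
  pressure drop grows quadratically with flow and depends on the
  artery/vein areas and the anastomosis angle (45° lower arm, 60° upper
  arm). Stenoses use a Young–Tsai-type law with viscous, quadratic and
  unsteady terms.
* **Personalization.** Radius profiles are delineated by the
  full-width-at-half-maximum criterion, cleaned by a running-median/MAD
  outlier rule, and fitted per artery (linear taper for the radial artery;
  a continuous three-phase line fit with a flat first segment for the
  subclavian–axillary–brachial chain). Venous radii come from ultrasound
  major/minor diameters; Doppler flows (always a [parabolic, flat] range)
  set the windkessel terminals.
* **Uncertainty.** Latin-hypercube sampling (1000 samples per parameter by
  default) over the in-/outflow-tract station diameters (±10% arterial,
  ±30% venous), a global diameter factor, and stenosis geometry; the
  prediction is the empirical 25th–75th percentile interval of the
  simulated arm inflow, compared with the measured postoperative flow
  range by closed-interval overlap.

## Worked example

Predict the postoperative flow for the packaged clean synthetic
radiocephalic (lower-arm) patient with a reduced Monte-Carlo budget:

```bash
$ vaflow uq --patient clean --samples-per-param 20 --seed 11 --dt 5e-3
deterministic arm inflow: 876.5 ml/min
25th-75th interval: [779.7, 897.0] ml/min (280 samples, 0 failed)
measured postop range: [834.1, 1668.3] ml/min -> overlap: True
```

The deterministic line is the arm inflow (cycle-averaged flow in the
proximal brachial artery) simulated at the nominal personalized geometry.
The interval is the 25th–75th percentile band over the Latin-hypercube
samples of the geometric inputs (here 14 parameters × 20 samples each).
The measured range is the synthetic patient's postoperative Doppler
measurement under the parabolic/flat velocity-profile ambiguity; the
verdict reports whether model and measurement overlap. The same analysis
is available from Python via `vaflow.predict_va_flow`, and
`vaflow synth` / `vaflow network` / `vaflow fit-radius` /
`vaflow simulate` expose the individual stages.

## Layout

* `src/vaflow/network.py` — generic heart-to-hand network, discretization,
  anastomosis/stenosis insertion
* `src/vaflow/solver.py` — pulse-wave solver, windkessels, lumped loss
  laws, baroreflex loop
* `src/vaflow/geometry.py` — FWHM delineation, profile cleaning, linear
  and three-phase radius fits
* `src/vaflow/personalize.py` — Doppler conversion, windkessel estimation,
  network personalization
* `src/vaflow/uncertainty.py` — Latin-hypercube Monte-Carlo, prediction
  intervals, overlap verdicts
* `src/vaflow/synthetic.py` — synthetic patients, waveforms, image stacks,
  Doppler traces
* `src/vaflow/pipeline.py` — end-to-end driver; `src/vaflow/cli.py` — CLI

See `docs/methods.md` for the modeling assumptions, numerical choices and
known limitations.
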