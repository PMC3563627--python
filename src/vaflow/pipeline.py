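"""End-to-end surgery-planning pipeline.

Chains the pieces the way the planning analysis runs in practice: clean the
angiography radius profiles, fit the per-artery radius models (linear taper
for the radial artery, three-phase with a flat first segment for the
subclavian-axillary-brachial chain), personalize the generic pre- and
postoperative networks, simulate the preoperative state to fix the
baroreflex pressure target, run the postoperative simulation with the
cardiac-output loop, and wrap the prediction in the geometric Monte-Carlo
uncertainty interval with the overlap verdict against the measured
postoperative flow range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import (clean_radius_profile, fit_linear_taper,
                       fit_three_phase)
from .network import (StenosisInsert, VascularNetwork,
                      build_generic_arm_network, insert_stenosis,
                      stenosis_from_severity)
from .personalize import (ArterialFitSet, MeasurementSet, personalize_network)
from .solver import SolverSettings, baroreflex_iterate, simulate
from .synthetic import SyntheticPatient, generate_inflow_waveform
from .uncertainty import (MCResult, assess_overlap, build_uncertainty_spec,
                          lhs_sample, run_monte_carlo,
                          DEFAULT_SAMPLES_PER_PARAMETER)


@dataclass
class PersonalizedCase:
    """Personalized pre/postoperative networks plus the baroreflex target."""

    network_pre: VascularNetwork
    network_post: VascularNetwork
    measurements: MeasurementSet
    target_mean_pressure: float     # preoperative simulated arch pressure
    preop_arm_inflow: float         # simulated, ml/min
    fits: ArterialFitSet


@dataclass
class PredictionResult:
    """Deterministic postoperative prediction and its uncertainty interval."""

    case: PersonalizedCase
    cardiac_output: float
    arm_inflow: float               # deterministic prediction, ml/min
    mc: Optional[MCResult]
    overlap: Optional[bool]


def fit_arterial_profiles(patient: SyntheticPatient,
                          clean: bool = True) -> ArterialFitSet:
    """Clean the angiography profiles and fit the arterial radius models."""
    prof_u = patient.radius_profiles["upper_chain"]
    prof_l = patient.radius_profiles["radial"]
    if clean:
        prof_u = clean_radius_profile(prof_u)
        prof_l = clean_radius_profile(prof_l)
    return ArterialFitSet(
        upper_chain=fit_three_phase(prof_u, constant_first=True),
        lower_artery=fit_linear_taper(prof_l))


def personalize_patient(patient: SyntheticPatient,
                        settings: Optional[SolverSettings] = None,
                        fits: Optional[ArterialFitSet] = None
                        ) -> PersonalizedCase:
    """Personalize the generic networks from the patient's modality data and
    fix the baroreflex target from the preoperative simulation."""
    s = settings or SolverSettings()
    fits = fits or fit_arterial_profiles(patient)
    pre = personalize_network(
        build_generic_arm_network(patient.config, preoperative=True),
        fits, patient.measurements)
    post = personalize_network(
        build_generic_arm_network(patient.config, preoperative=False),
        fits, patient.measurements)
    waveform = generate_inflow_waveform()
    sol = simulate(pre, waveform, settings=s)
    return PersonalizedCase(
        network_pre=pre, network_post=post,
        measurements=patient.measurements,
        target_mean_pressure=sol.mean_pressure("n_arch"),
        preop_arm_inflow=sol.mean_segment_flow("brachial_prox", "proximal"),
        fits=fits)


def predict_va_flow(patient: SyntheticPatient,
                    samples_per_parameter: int = DEFAULT_SAMPLES_PER_PARAMETER,
                    seed: Optional[int] = None,
                    settings: Optional[SolverSettings] = None,
                    mode: str = "pulsatile",
                    with_uncertainty: bool = True,
                    stenoses: Optional[Sequence[tuple[str, float,
                                                      StenosisInsert]]] = None,
                    case: Optional[PersonalizedCase] = None
                    ) -> PredictionResult:
    """Predict the postoperative arm inflow for a synthetic patient.

    Returns the deterministic (nominal-geometry) prediction and, when
    ``with_uncertainty``, the Latin-hypercube Monte-Carlo 25th-75th
    percentile interval plus the overlap verdict against the measured
    postoperative flow range. ``stenoses`` optionally augments the model
    with identified narrowings (vessel, position, insert).
    """
    s = settings or SolverSettings()
    case = case or personalize_patient(patient, settings=s)
    post = case.network_post
    if stenoses:
        for vessel, position, insert in stenoses:
            post = insert_stenosis(post, vessel, position, insert)
    waveform = generate_inflow_waveform()
    det = baroreflex_iterate(post, waveform, case.target_mean_pressure,
                             settings=s)
    q_det = det.solution.mean_segment_flow("brachial_prox", "proximal")
    mc = verdict = None
    if with_uncertainty:
        spec = build_uncertainty_spec(post)
        samples = lhs_sample(spec, samples_per_parameter, seed=seed)
        mc = run_monte_carlo(post, spec, samples, waveform,
                             case.target_mean_pressure, settings=s,
                             mode=mode, seed=seed)
        if patient.measurements.postoperative_inflow is not None:
            verdict = assess_overlap(mc.interval,
                                     patient.measurements.postoperative_inflow)
    return PredictionResult(case=case, cardiac_output=det.cardiac_output,
                            arm_inflow=q_det, mc=mc, overlap=verdict)


def detected_stenosis_insert(patient: SyntheticPatient,
                             network: Optional[VascularNetwork] = None
                             ) -> Optional[tuple[str, float, StenosisInsert]]:
    """The stenosis placement 'identified on the angiography' for a synthetic
    patient: severity/length/position read off the true narrowing, reference
    area from the (personalized, if given) model network."""
    if patient.stenosis is None:
        return None
    st = patient.stenosis
    net = network or build_generic_arm_network(patient.config,
                                               preoperative=False)
    ref_r = net.segments[st.vessel].radius_at(st.position + st.length / 2)
    insert = stenosis_from_severity(st.severity, float(np.pi) * ref_r ** 2,
                                    st.length)
    return (st.vessel, st.position, insert)
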