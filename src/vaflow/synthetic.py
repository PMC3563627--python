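"""Synthetic patients for end-to-end testing of the planning pipeline.

Each synthetic patient consists of a ground-truth vascular geometry (linear
tapers per vessel, a flat subclavian run, optional localized stenosis),
angiography-like centerline radius profiles (1 mm spacing, multiplicative
noise, outlier spikes, configurable modality bias), ultrasound-protocol
measurements (station diameters, elliptical venous major/minor axes, Doppler
velocity records), and a model-consistent ground-truth postoperative flow
obtained by simulating the true network. Regeneration with the same seed is
bit-identical.

The configurable modality biases emulate the reported systematic
differences between non-contrast MR angiography and ultrasound diameters
(arterial about +9%, venous about +38% for MRA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .geometry import CrossSection, RadiusProfile, DEFAULT_PIXEL_SIZE_MM
from .network import (VAConfiguration, VascularNetwork,
                      build_generic_arm_network, insert_stenosis,
                      stenosis_from_severity)
from .personalize import (DopplerRecord, FlowRange, MeasurementSet,
                          compute_windkessel, REFERENCE_CARDIAC_OUTPUT_MLMIN,
                          _UPPER_CHAIN, _UPPER_STATIONS, _LOWER_CHAIN,
                          _LOWER_STATIONS, chain_station_positions)
from .network import WindkesselTerminal
from .solver import (FlowWaveform, SolverSettings, baroreflex_iterate,
                     simulate)

# reported systematic MRA-vs-US diameter biases (fractional overestimates)
MRA_ARTERIAL_BIAS = 0.09
MRA_VENOUS_BIAS = 0.38

DEFAULT_RADIUS_NOISE = 0.05       # multiplicative sigma on profile samples
DEFAULT_OUTLIER_RATE = 0.02       # fraction of spike samples
OUTLIER_FACTOR_RANGE = (2.0, 4.0)  # spike magnitude, multiples of local radius

# true preoperative flow distribution (ml/min), lower-arm defaults
TRUE_RADIAL_OUTFLOW = 35.0
TRUE_ULNAR_OUTFLOW = 45.0
TRUE_MUSCLE_FLOW = 40.0
TRUE_MAP_MMHG = 93.0

VENOUS_ASPECT_RATIO = 1.3         # major/minor of the elliptical vein section


@dataclass
class BiasSpec:
    """Systematic diameter biases of the synthetic modalities (fractions;
    positive = the modality overestimates the true diameter)."""

    mra_arterial: float = 0.0
    mra_venous: float = MRA_VENOUS_BIAS
    us_arterial: float = 0.0
    us_venous: float = 0.0


@dataclass
class StenosisSpec:
    """A true localized narrowing: area severity in [0, 1), length (cm),
    position (cm from the vessel's proximal end)."""

    severity: float = 0.75
    length: float = 3.5
    position: float = 4.0
    vessel: str = "radial_prox"


@dataclass
class SyntheticPatient:
    """One complete synthetic case; all modality data derive from the
    ground-truth geometry and flows."""

    seed: int
    config: VAConfiguration
    true_network_pre: VascularNetwork
    true_network_post: VascularNetwork
    true_station_radii: dict[str, float]
    radius_profiles: dict[str, RadiusProfile]
    mra_venous_diameters: dict[str, tuple[float, float]]
    measurements: MeasurementSet
    true_flows: dict[str, float]
    true_preop_target_pressure: float
    true_postop_inflow: float
    stenosis: Optional[StenosisSpec]
    bias: BiasSpec
    noise_sigma: float


# ---------------------------------------------------------------------------
# Waveform
# ---------------------------------------------------------------------------

def generate_inflow_waveform(cardiac_output: float = REFERENCE_CARDIAC_OUTPUT_MLMIN,
                             period: float = 1.0,
                             systolic_fraction: float = 0.35,
                             diastolic_level: float = 0.2,
                             n_samples: int = 1000) -> FlowWaveform:
    """Characteristic aortic inflow: a raised-sine systolic pulse over a low
    diastolic plateau, scaled so the time average equals the cardiac output
    (ml/min) to machine precision. Non-negative throughout the cycle."""
    if cardiac_output <= 0:
        raise ValueError("cardiac output must be positive")
    t = np.linspace(0.0, period, n_samples + 1)
    ts = systolic_fraction * period
    shape = np.full_like(t, diastolic_level)
    sys_mask = t <= ts
    shape[sys_mask] += np.sin(np.pi * t[sys_mask] / ts) ** 2
    mean = np.trapezoid(shape, t) / period
    return FlowWaveform(period, t, shape * (cardiac_output / mean))


# ---------------------------------------------------------------------------
# Imaging
# ---------------------------------------------------------------------------

def generate_cross_section_stack(radius_fn: Callable[[np.ndarray], np.ndarray],
                                 positions_mm: np.ndarray,
                                 pixel_size: float = DEFAULT_PIXEL_SIZE_MM,
                                 noise: float = 0.0,
                                 lumen_intensity: float = 200.0,
                                 background_intensity: float = 20.0,
                                 rng: Optional[np.random.Generator] = None
                                 ) -> list[CrossSection]:
    """Bright-disk cross-sections of a vessel at the given centerline
    positions: intensity ramps linearly over one pixel at the lumen edge so
    the half-maximum crossing sits exactly at the true radius."""
    rng = rng or np.random.default_rng(0)
    positions_mm = np.asarray(positions_mm, dtype=float)
    radii = np.atleast_1d(np.asarray(radius_fn(positions_mm), dtype=float))
    if np.any(radii < 2.0 * pixel_size):
        raise ValueError("true radius below the resolution limit (2 px)")
    half = int(math.ceil((radii.max() + 5.0 * pixel_size) / pixel_size))
    n = 2 * half + 1
    rr, cc = np.indices((n, n))
    d_px = np.hypot(rr - half, cc - half)
    sections = []
    for r_mm in radii:
        cover = np.clip(r_mm / pixel_size - d_px + 0.5, 0.0, 1.0)
        img = background_intensity + (lumen_intensity - background_intensity) * cover
        if noise > 0:
            img = img + noise * lumen_intensity * rng.standard_normal(img.shape)
        sections.append(CrossSection(image=img, pixel_size=pixel_size,
                                     center=(half, half)))
    return sections


# ---------------------------------------------------------------------------
# Doppler
# ---------------------------------------------------------------------------

@dataclass
class VelocityTrace:
    """Synthetic Doppler maximum-velocity curve over one cardiac cycle."""

    times: np.ndarray           # s
    vmax: np.ndarray            # cm/s
    area: float                 # cm^2

    @property
    def vmax_mean(self) -> float:
        return float(np.trapezoid(self.vmax, self.times)
                     / (self.times[-1] - self.times[0]))

    def record(self) -> DopplerRecord:
        return DopplerRecord(vmax_mean=self.vmax_mean, area=self.area)


def generate_doppler_trace(true_flow: float, area: float,
                           profile: str = "parabolic",
                           period: float = 1.0) -> VelocityTrace:
    """Maximum-velocity trace whose time mean inverts the Doppler mean-flow
    formula for the chosen velocity profile, so the derived flow range
    brackets the true flow (parabolic truth sits on the low bound, flat
    truth on the high bound)."""
    if area <= 0:
        raise ValueError("area must be positive")
    factor = {"parabolic": 0.5, "flat": 1.0}[profile]
    vmax_mean = (true_flow / 60.0) / (factor * area)  # cm/s
    shape = generate_inflow_waveform(cardiac_output=60.0, period=period)
    return VelocityTrace(times=shape.times,
                         vmax=shape.values / 60.0 * vmax_mean, area=area)


# ---------------------------------------------------------------------------
# Patient generation
# ---------------------------------------------------------------------------

def _true_chain_radius_fn(stations: dict[str, float],
                          positions: list[float], labels: list[str],
                          flat_until: Optional[int] = None
                          ) -> Callable[[np.ndarray], np.ndarray]:
    vals = np.array([stations[lbl] for lbl in labels])
    pos = np.array(positions, dtype=float)
    return lambda s: np.interp(np.asarray(s, dtype=float), pos, vals)


def _station_positions_mm(net: VascularNetwork) -> dict[str, list[float]]:
    return {"upper": chain_station_positions(net, _UPPER_CHAIN),
            "lower": chain_station_positions(net, _LOWER_CHAIN)}


def generate_patient(seed: int,
                     config: Optional[VAConfiguration] = None,
                     stenosis: Optional[StenosisSpec] = None,
                     bias: Optional[BiasSpec] = None,
                     noise_sigma: float = DEFAULT_RADIUS_NOISE,
                     outlier_rate: float = DEFAULT_OUTLIER_RATE,
                     patient_variability: float = 0.05,
                     profile_truth: str = "parabolic",
                     solver_settings: Optional[SolverSettings] = None
                     ) -> SyntheticPatient:
    """Generate a complete synthetic patient.

    The true geometry perturbs the generic station radii by a lognormal
    per-station factor (sigma ``patient_variability``), keeps the subclavian
    and axillary run flat (so the upper-arm chain is exactly three-phase
    piecewise linear), and optionally carves a stenosis into the true
    network and its radius profile. The ground-truth postoperative inflow is
    computed by simulating the true postoperative network with the
    cardiac-output baroreflex against the true preoperative arch pressure.
    """
    config = config or VAConfiguration()
    bias = bias or BiasSpec(mra_arterial=0.0, mra_venous=MRA_VENOUS_BIAS)
    rng = np.random.default_rng(seed)
    s = solver_settings or SolverSettings(dt=2.5e-3, n_cycles=25)

    pre = build_generic_arm_network(config, preoperative=True)
    post = build_generic_arm_network(config, preoperative=False)

    # --- true station radii ------------------------------------------------
    true_radii: dict[str, float] = {}
    for label in post.stations:
        if not any(sn in post.segments for sn, _ in post.stations[label]):
            continue
        factor = math.exp(patient_variability * rng.standard_normal())
        true_radii[label] = post.get_station_radius(label) * factor
    # flat subclavian/axillary run -> upper chain is exactly three-phase
    if all(k in true_radii for k in ("A_SUB0", "A_SUB", "A_AX")):
        flat = np.mean([true_radii["A_SUB0"], true_radii["A_SUB"],
                        true_radii["A_AX"]])
        true_radii["A_SUB0"] = true_radii["A_SUB"] = true_radii["A_AX"] = flat
    for net in (pre, post):
        for label, r in true_radii.items():
            if any(sn in net.segments for sn, _ in net.stations.get(label, [])):
                net.set_station_radius(label, r)

    # --- true flows and terminals -----------------------------------------
    flow_scale = math.exp(0.5 * patient_variability * rng.standard_normal())
    q_rad = TRUE_RADIAL_OUTFLOW * flow_scale
    q_uln = TRUE_ULNAR_OUTFLOW * flow_scale
    q_mus = TRUE_MUSCLE_FLOW * flow_scale
    q_in = q_rad + q_uln + q_mus
    p_map = TRUE_MAP_MMHG + 4.0 * rng.standard_normal()
    for net in (pre, post):
        for node, name, q, r in (
                ("n_wrist", "hand_radial", q_rad, net.segments["radial_dist"].r_d),
                ("n_ulnar_end", "hand_ulnar", q_uln, net.segments["ulnar_a"].r_d),
                ("n_br_mid", "arm_muscle", q_mus, 1.5)):
            z, rr, cc = compute_windkessel(p_map, q, r)
            net.terminals[node] = WindkesselTerminal(node=node, Z=z, R=rr,
                                                     C=cc, name=name)
        z, rr, cc = compute_windkessel(
            p_map, REFERENCE_CARDIAC_OUTPUT_MLMIN - q_in,
            net.segments["aortic_arch"].r_d, youngs_kpa=400.0)
        net.terminals["n_arch"] = WindkesselTerminal(node="n_arch", Z=z, R=rr,
                                                     C=cc, name="rest_of_body")

    # chain/station geometry snapshot (before any stenosis splits segments)
    pos = _station_positions_mm(post)
    lower_seg_lengths = {name: post.segments[name].length
                         for name in _LOWER_CHAIN}

    # --- true stenosis -----------------------------------------------------
    if stenosis is not None:
        ref_r = pre.segments[stenosis.vessel].radius_at(
            stenosis.position + stenosis.length / 2.0)
        insert = stenosis_from_severity(stenosis.severity,
                                        math.pi * ref_r ** 2, stenosis.length)
        pre = insert_stenosis(pre, stenosis.vessel, stenosis.position, insert)
        post = insert_stenosis(post, stenosis.vessel, stenosis.position, insert)

    # --- ground-truth hemodynamics ----------------------------------------
    waveform = generate_inflow_waveform()
    sol_pre = simulate(pre, waveform, settings=s)
    p_target = sol_pre.mean_pressure("n_arch")
    post_res = baroreflex_iterate(post, waveform, p_target, settings=s)
    q_post_true = post_res.solution.mean_segment_flow("brachial_prox",
                                                      "proximal")

    # --- angiography-like radius profiles ---------------------------------
    upper_fn = _true_chain_radius_fn(true_radii, pos["upper"], _UPPER_STATIONS)
    lower_fn_base = _true_chain_radius_fn(true_radii, pos["lower"],
                                          _LOWER_STATIONS)
    if stenosis is not None and stenosis.vessel in _LOWER_CHAIN:
        # arc position of the dip within the lower chain, mm
        offset = 0.0
        for segname in _LOWER_CHAIN:
            if segname == stenosis.vessel:
                break
            offset += lower_seg_lengths[segname] * 10.0
        dip_lo = offset + stenosis.position * 10.0
        dip_hi = dip_lo + stenosis.length * 10.0
        shrink = math.sqrt(1.0 - stenosis.severity)

        def lower_fn(sv):
            sv = np.asarray(sv, dtype=float)
            base = lower_fn_base(sv)
            in_dip = (sv >= dip_lo) & (sv <= dip_hi)
            return np.where(in_dip, base * shrink, base)
    else:
        lower_fn = lower_fn_base

    def _noisy_profile(fn, length_mm):
        sv = np.arange(0.0, length_mm + 0.5, 1.0)
        r = fn(sv) * (1.0 + bias.mra_arterial)
        r = r * (1.0 + noise_sigma * rng.standard_normal(sv.size))
        spikes = rng.random(sv.size) < outlier_rate
        r = np.where(spikes,
                     r * rng.uniform(*OUTLIER_FACTOR_RANGE, size=sv.size), r)
        return RadiusProfile(positions=sv, radii=np.abs(r))

    profiles = {"upper_chain": _noisy_profile(upper_fn, pos["upper"][-1]),
                "radial": _noisy_profile(lower_fn, pos["lower"][-1])}

    # --- US measurement set ------------------------------------------------
    arterial = {}
    venous = {}
    mra_venous = {}
    for label, r in true_radii.items():
        if label.startswith("A_"):
            arterial[label] = 2.0 * r * (1.0 + bias.us_arterial) \
                * (1.0 + 0.3 * noise_sigma * rng.standard_normal())
        else:
            asp = math.sqrt(VENOUS_ASPECT_RATIO)
            jitter = 1.0 + 0.3 * noise_sigma * rng.standard_normal()
            venous[label] = (2.0 * r * asp * (1.0 + bias.us_venous) * jitter,
                             2.0 * r / asp * (1.0 + bias.us_venous) * jitter)
            mra_venous[label] = (2.0 * r * asp * (1.0 + bias.mra_venous),
                                 2.0 * r / asp * (1.0 + bias.mra_venous))

    def _area_cm2(r_mm):
        return math.pi * (r_mm / 10.0) ** 2

    doppler = {
        "arm_inflow": generate_doppler_trace(
            q_in, _area_cm2(true_radii["A_BR1"]), profile_truth).record(),
        "radial_outflow": generate_doppler_trace(
            q_rad, _area_cm2(true_radii["A_RA3"]), profile_truth).record(),
        "ulnar_outflow": generate_doppler_trace(
            q_uln, _area_cm2(true_radii["A_UL2"]), profile_truth).record(),
    }
    factor = {"parabolic": 0.5, "flat": 1.0}[profile_truth]
    post_range = FlowRange(low=0.5 * q_post_true / factor,
                           high=q_post_true / factor)
    measurements = MeasurementSet(
        arterial_diameters=arterial, venous_diameters=venous,
        doppler=doppler, mean_arterial_pressure=p_map,
        postoperative_inflow=post_range)

    return SyntheticPatient(
        seed=seed, config=config, true_network_pre=pre,
        true_network_post=post, true_station_radii=true_radii,
        radius_profiles=profiles, mra_venous_diameters=mra_venous,
        measurements=measurements,
        true_flows={"arm_inflow": q_in, "radial": q_rad, "ulnar": q_uln,
                    "muscle": q_mus},
        true_preop_target_pressure=p_target,
        true_postop_inflow=q_post_true, stenosis=stenosis, bias=bias,
        noise_sigma=noise_sigma)


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

CANONICAL_SEEDS = {"clean": 101, "mild": 202, "severe": 303}


def canonical_patient(kind: str,
                      solver_settings: Optional[SolverSettings] = None
                      ) -> SyntheticPatient:
    """The three packaged case archetypes (lower-arm radiocephalic):
    'clean' (no stenosis, low noise, zero modality bias), 'mild' (25%
    narrowing over 5 cm) and 'severe' (75% stenosis over 3.5 cm in the
    arterial inflow tract)."""
    if kind not in CANONICAL_SEEDS:
        raise ValueError(f"unknown canonical patient {kind!r}")
    sten = {"clean": None,
            "mild": StenosisSpec(severity=0.25, length=5.0, position=3.0,
                                 vessel="radial_prox"),
            "severe": StenosisSpec(severity=0.75, length=3.5, position=4.0,
                                   vessel="radial_prox")}[kind]
    return generate_patient(seed=CANONICAL_SEEDS[kind], stenosis=sten,
                            bias=BiasSpec(mra_arterial=0.0,
                                          mra_venous=MRA_VENOUS_BIAS),
                            noise_sigma=0.02, outlier_rate=0.01,
                            solver_settings=solver_settings)
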