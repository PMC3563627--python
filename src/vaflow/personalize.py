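"""Map clinical measurements onto the generic network.

Personalization is limited to arm geometry and arm flows: fitted arterial
radius models and ultrasound venous diameters overwrite the generic radii at
the protocol stations, measured Doppler flows set the peripheral windkessel
terminals, and the distributed (muscle) flow is estimated by subtracting the
distal arterial outflows from the arm inflow.

Doppler flows carry an irreducible velocity-profile ambiguity: the mean flow
is the mean maximum-velocity times area times a profile correction factor of
0.5 (parabolic) or 1.0 (flat), so every measured flow is a two-point range.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from . import units
from .geometry import LinearFit, ThreePhaseFit, sample_at_stations
from .network import (VascularNetwork, WindkesselTerminal,
                      VENOUS_OUTLET_PRESSURE_MMHG)

REFERENCE_CARDIAC_OUTPUT_MLMIN = 5100.0

#: peripheral windkessel RC time constant (s), documented package constant
PERIPHERAL_TIME_CONSTANT_S = 1.5

#: Young's modulus (kPa) used for the characteristic impedance of distal
#: arterial beds, and notional radius of the muscle-bed feeding branch (mm)
TERMINAL_YOUNGS_KPA = 800.0
MUSCLE_TERMINAL_RADIUS_MM = 1.5


class PersonalizationError(ValueError):
    """Raised when required measurements are missing or inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FlowRange:
    """Measured flow as a [parabolic, flat] profile-assumption range, ml/min."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low < 0 or self.high < self.low:
            raise PersonalizationError("flow range must satisfy 0 <= low <= high")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)

    def value(self, scenario: str = "mid") -> float:
        return {"parabolic": self.low, "flat": self.high,
                "mid": self.midpoint}[scenario]


@dataclass
class DopplerRecord:
    """One Doppler measurement: time-mean of the maximum-velocity curve
    (cm/s) and the vessel cross-sectional area (cm^2)."""

    vmax_mean: float
    area: float

    def __post_init__(self) -> None:
        if self.vmax_mean < 0 or self.area < 0:
            raise PersonalizationError("Doppler inputs must be non-negative")


@dataclass
class MeasurementSet:
    """US-protocol measurements for one patient.

    ``arterial_diameters``: station label -> diameter (mm).
    ``venous_diameters``: station label -> (major, minor) diameters (mm).
    ``doppler``: keys 'arm_inflow', 'radial_outflow', 'ulnar_outflow'.
    ``postoperative_inflow``: measured post-surgery arm-inflow range, if any.
    """

    arterial_diameters: dict[str, float] = field(default_factory=dict)
    venous_diameters: dict[str, tuple[float, float]] = field(default_factory=dict)
    doppler: dict[str, DopplerRecord] = field(default_factory=dict)
    mean_arterial_pressure: float = 93.0  # mmHg
    postoperative_inflow: Optional[FlowRange] = None

    def __post_init__(self) -> None:
        for label, d in self.arterial_diameters.items():
            if d <= 0:
                raise PersonalizationError(f"diameter at {label} must be > 0")
        for label, (major, minor) in self.venous_diameters.items():
            if not (major >= minor > 0):
                raise PersonalizationError(
                    f"venous station {label} needs major >= minor > 0")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def doppler_mean_flow(vmax_mean: float, area: float) -> FlowRange:
    """Mean-flow range (ml/min) from a Doppler mean maximum velocity (cm/s)
    and lumen area (cm^2): the parabolic profile factor 0.5 gives the low
    bound, the flat factor 1.0 the high bound."""
    if vmax_mean < 0 or area < 0:
        raise PersonalizationError("Doppler inputs must be non-negative")
    q_flat = vmax_mean * area * 60.0  # cm^3/s -> ml/min
    return FlowRange(low=0.5 * q_flat, high=q_flat)


def estimate_distributed_flow(q_in: FlowRange, q_radial: FlowRange,
                              q_ulnar: FlowRange) -> FlowRange:
    """Distributed (muscle) flow = arm inflow minus radial and ulnar
    outflows, componentwise per profile scenario; negative components are
    clipped to zero with a warning."""
    low = q_in.low - q_radial.low - q_ulnar.low
    high = q_in.high - q_radial.high - q_ulnar.high
    if low < 0 or high < 0:
        warnings.warn("distal outflows exceed arm inflow; "
                      "distributed flow clipped at 0")
        low, high = max(low, 0.0), max(high, 0.0)
    return FlowRange(low=min(low, high), high=max(low, high))


def compute_windkessel(p_mean: float, q_mean: float, radius: float,
                       p_out: float = VENOUS_OUTLET_PRESSURE_MMHG,
                       youngs_kpa: float = TERMINAL_YOUNGS_KPA,
                       tau_s: float = PERIPHERAL_TIME_CONSTANT_S
                       ) -> tuple[float, float, float]:
    """Three-element windkessel parameters from the mean pressure (mmHg),
    mean outflow (ml/min) and terminal radius (mm).

    Z is the characteristic impedance rho*c/A with the Moens-Korteweg wave
    speed at the terminal radius; R absorbs the remaining mean resistance
    (p_mean - p_out)/q_mean - Z, floored at 0 (reported); C follows from a
    fixed peripheral time constant tau = R*C.
    Returns (Z, R, C) in (mmHg.min/ml, mmHg.min/ml, ml/mmHg).
    """
    if q_mean <= 0:
        raise PersonalizationError("windkessel estimation needs q_mean > 0")
    c = units.moens_korteweg_speed(radius, 0.1 * radius, youngs_kpa)
    area = math.pi * units.mm_to_m(radius) ** 2
    z = units.resistance_to_clinical(units.BLOOD_DENSITY * c / area)
    r_total = (p_mean - p_out) / q_mean
    r = r_total - z
    if r < 0:
        warnings.warn("terminal pressure head below characteristic-impedance "
                      "drop; peripheral resistance floored at 0")
        r = 0.0
    cap = (tau_s / 60.0) / r if r > 0 else 0.0
    return z, r, cap


def venous_radius_from_us(major: float, minor: float) -> float:
    """Area-equivalent radius (mm) of an elliptical venous cross-section:
    sqrt(major * minor) / 2 preserves the ellipse area."""
    if not (major >= minor > 0):
        raise PersonalizationError("need major >= minor > 0")
    return math.sqrt(major * minor) / 2.0


@dataclass
class ArterialFitSet:
    """Fitted radius models for the arterial inflow tract.

    ``upper_chain`` covers the subclavian-axillary-brachial run (three-phase
    fit with a flat first segment); ``lower_artery`` covers the radial artery
    (linear taper). Fit positions are arc length in mm from the chain start.
    """

    upper_chain: Optional[ThreePhaseFit] = None
    lower_artery: Optional[LinearFit] = None


_UPPER_CHAIN = ["subclavian_a", "axillary_a", "brachial_prox", "brachial_dist"]
_UPPER_STATIONS = ["A_SUB0", "A_SUB", "A_AX", "A_BR1", "A_BR2"]
_LOWER_CHAIN = ["radial_prox", "radial_dist"]
_LOWER_STATIONS = ["A_RA1", "A_RA2", "A_RA3"]


def chain_station_positions(network: VascularNetwork,
                            chain: list[str]) -> list[float]:
    """Arc-length positions (mm) of the chain's boundary stations, computed
    from the segment lengths (0 at the chain's proximal end)."""
    pos = [0.0]
    acc = 0.0
    for name in chain:
        acc += network.segments[name].length * 10.0  # cm -> mm
        pos.append(acc)
    return pos


def personalize_network(generic_network: VascularNetwork,
                        arterial_fits: ArterialFitSet,
                        measurements: MeasurementSet,
                        flow_scenario: str = "mid",
                        cardiac_output: float = REFERENCE_CARDIAC_OUTPUT_MLMIN
                        ) -> VascularNetwork:
    """Overwrite the generic geometry and terminals with patient data.

    Arterial station radii come from the fitted radius models (falling back
    to per-station measured diameters when a fit does not cover a station);
    venous station radii come from the US major/minor diameters; windkessel
    terminals are re-estimated from the Doppler flow ranges at the measured
    mean pressure. Deterministic and idempotent for fixed inputs.
    """
    net = copy.deepcopy(generic_network)

    # -- arterial geometry --------------------------------------------------
    if arterial_fits.upper_chain is not None:
        pos = chain_station_positions(net, _UPPER_CHAIN)
        radii = sample_at_stations(arterial_fits.upper_chain, pos)
        for label, r in zip(_UPPER_STATIONS, radii):
            if label in net.stations:
                net.set_station_radius(label, float(r))
    if arterial_fits.lower_artery is not None and \
            all(s in net.segments for s in _LOWER_CHAIN):
        pos = chain_station_positions(net, _LOWER_CHAIN)
        radii = sample_at_stations(arterial_fits.lower_artery, pos)
        for label, r in zip(_LOWER_STATIONS, radii):
            if label in net.stations:
                net.set_station_radius(label, float(r))
    for label, diam in measurements.arterial_diameters.items():
        if label in net.stations:
            seg, end = net.stations[label][0]
            if seg in net.segments and not net.segments[seg].measured:
                net.set_station_radius(label, diam / 2.0)

    # -- venous geometry (postoperative networks) ---------------------------
    for label, (major, minor) in measurements.venous_diameters.items():
        if label in net.stations:
            present = [s for s, _ in net.stations[label] if s in net.segments]
            if present:
                net.set_station_radius(label, venous_radius_from_us(major, minor))

    required = {"arm_inflow", "radial_outflow", "ulnar_outflow"}
    missing = required - set(measurements.doppler)
    if missing:
        raise PersonalizationError(f"missing Doppler records: {sorted(missing)}")
    q_in = doppler_mean_flow(**vars(measurements.doppler["arm_inflow"]))
    q_rad = doppler_mean_flow(**vars(measurements.doppler["radial_outflow"]))
    q_uln = doppler_mean_flow(**vars(measurements.doppler["ulnar_outflow"]))
    q_muscle = estimate_distributed_flow(q_in, q_rad, q_uln)

    p_mean = measurements.mean_arterial_pressure
    sc = flow_scenario

    def _wk(node: str, name: str, q: float, radius_mm: float) -> None:
        z, r, cap = compute_windkessel(p_mean, q, radius_mm)
        net.terminals[node] = WindkesselTerminal(node=node, Z=z, R=r, C=cap,
                                                name=name)

    _wk("n_wrist", "hand_radial", max(q_rad.value(sc), 1.0),
        net.segments["radial_dist"].r_d)
    _wk("n_ulnar_end", "hand_ulnar", max(q_uln.value(sc), 1.0),
        net.segments["ulnar_a"].r_d)
    _wk("n_br_mid", "arm_muscle", max(q_muscle.value(sc), 1.0),
        MUSCLE_TERMINAL_RADIUS_MM)

    # rest-of-body terminal balances the reference cardiac output so that the
    # preoperative aortic-arch mean pressure reproduces the measured one
    q_body = cardiac_output - q_in.value(sc)
    if q_body <= 0:
        raise PersonalizationError("arm inflow exceeds the cardiac output")
    z_b, r_b, c_b = compute_windkessel(p_mean, q_body,
                                       net.segments["aortic_arch"].r_d,
                                       youngs_kpa=400.0)
    net.terminals["n_arch"] = WindkesselTerminal(node="n_arch", Z=z_b, R=r_b,
                                                 C=c_b, name="rest_of_body")

    net.refresh_anastomosis_areas()
    net.validate()
    return net
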