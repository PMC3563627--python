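"""Unit conversions and physical constants.

Interface convention throughout the package: pressures in mmHg, flows in
ml/min, radii and wall thickness in mm, lengths in cm, Young's moduli in kPa,
windkessel impedance/resistance in mmHg·min/ml and compliance in ml/mmHg.
The solver works in SI internally; these helpers form the single boundary
layer where conversion happens.
"""

from __future__ import annotations

# Blood properties (documented package constants)
BLOOD_DENSITY = 1050.0  # kg/m^3
BLOOD_VISCOSITY = 3.5e-3  # Pa.s

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322

ML_PER_MIN_PER_M3S = 6.0e7  # 1 m^3/s = 6e7 ml/min
M3S_PER_ML_MIN = 1.0 / ML_PER_MIN_PER_M3S


def mmhg_to_pa(p: float) -> float:
    return p * PA_PER_MMHG


def pa_to_mmhg(p: float) -> float:
    return p * MMHG_PER_PA


def mlmin_to_m3s(q: float) -> float:
    return q * M3S_PER_ML_MIN


def m3s_to_mlmin(q: float) -> float:
    return q * ML_PER_MIN_PER_M3S


def mm_to_m(x: float) -> float:
    return x * 1e-3


def cm_to_m(x: float) -> float:
    return x * 1e-2


def kpa_to_pa(x: float) -> float:
    return x * 1e3


# Resistance: mmHg·min/ml <-> Pa·s/m^3
R_SI_PER_CLINICAL = PA_PER_MMHG * 6.0e7  # (mmHg.min/ml) expressed in Pa.s/m^3


def resistance_to_si(r: float) -> float:
    return r * R_SI_PER_CLINICAL


def resistance_to_clinical(r: float) -> float:
    return r / R_SI_PER_CLINICAL


# Compliance: ml/mmHg <-> m^3/Pa
C_SI_PER_CLINICAL = 1e-6 / PA_PER_MMHG


def compliance_to_si(c: float) -> float:
    return c * C_SI_PER_CLINICAL


def compliance_to_clinical(c: float) -> float:
    return c / C_SI_PER_CLINICAL


def moens_korteweg_speed(radius_mm: float, wall_mm: float, youngs_kpa: float,
                         rho: float = BLOOD_DENSITY) -> float:
    """Pulse wave speed c = sqrt(E h / (2 rho r)) of a thin-walled elastic
    tube, in m/s."""
    e = kpa_to_pa(youngs_kpa)
    h = mm_to_m(wall_mm)
    r = mm_to_m(radius_mm)
    return (e * h / (2.0 * rho * r)) ** 0.5
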