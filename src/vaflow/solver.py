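"""1D pulse-wave dynamics on a vascular network.

Model
-----
Each vessel segment is divided into short (<= 5 cm) 1D elements. For every
element the linearized 1D mass and momentum balances with Poiseuille
friction and a thin-wall linear-elastic tube law reduce to a
resistance-inertance-compliance transmission-line cell:

    viscous resistance   R  = integral 8 mu / (pi r(x)^4) dx        (exact
                              for a linear taper),
    blood inertance      L  = rho * integral dx / A(x),
    wall compliance      C  = integral dA/dp dx,  dA/dp = 2 pi r^3 / (E h),

with the compliance lumped half to each end node. The continuum limit of
this ladder propagates pulses at the Moens-Korteweg speed
c = sqrt(E h / (2 rho r)) and its steady limit is exact Poiseuille flow.

Arterial ends carry three-element windkessel terminals (Z series, R || C,
draining to an outlet pressure). The anastomosis and stenosis inserts enter
as lumped nonlinear resistors whose pressure drop grows quadratically with
flow (plus viscous/inertial terms for the stenosis).

The assembled differential-algebraic system in the unknowns
[node pressures, element flows, windkessel states] is integrated by backward
Euler; the nonlinear loss coefficients are treated semi-implicitly (Picard,
coefficient from the previous time level). Cycles are repeated until the
cycle-mean pressures are periodic to within a tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import units
from .network import (AnastomosisJunction, StenosisInsert, VascularNetwork,
                      discretize_segment, MAX_ELEMENT_LENGTH_CM)

# Anastomosis loss-law constants (packaged defaults; the tested contract is
# zero drop at zero flow, superlinear growth, monotone in angle, and
# anti-monotone in each area)
ANASTOMOSIS_CV = 1.0   # weight of the angle-dependent venous inflow loss
ANASTOMOSIS_CA = 0.3   # weight of the arterial expansion loss
ANASTOMOSIS_EFFECTIVE_LENGTH_CM = 1.0  # inertial length of the connection

# Stenosis loss-law constants (Young-Tsai-type form). The viscous
# coefficient Kv = 32 (L_s/D_0) (A_0/A_s)^2 makes the A_s == A_0 limit
# collapse exactly onto the straight-tube Poiseuille drop.
STENOSIS_KT = 1.52     # turbulent/quadratic coefficient
STENOSIS_KU = 1.2      # unsteady (inertial) coefficient
STENOSIS_OFFSET_MMHG = 0.0  # constant offset term (default none)

_WK_R_FLOOR_SI = 1e5   # Pa.s/m^3; numerical floor for peripheral resistance
_WK_Z_FLOOR_SI = 1.0


class ConvergenceError(RuntimeError):
    """Raised when the periodic steady state or an iteration fails to
    converge within its budget."""


# ---------------------------------------------------------------------------
# Waveform and constitutive law
# ---------------------------------------------------------------------------

@dataclass
class FlowWaveform:
    """Periodic inflow waveform q(t) in ml/min over one period T (s).

    ``times`` spans [0, T] with ``values[0] == values[-1]``; evaluation is
    periodic with linear interpolation. The ``mean`` is the exact
    trapezoidal time average over one period.
    """

    period: float
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times[0] != 0.0 or abs(self.times[-1] - self.period) > 1e-12:
            raise ValueError("waveform times must span [0, period]")

    @property
    def mean(self) -> float:
        """Time-average flow over one period, ml/min."""
        return float(np.trapezoid(self.values, self.times) / self.period)

    def __call__(self, t) -> np.ndarray:
        return np.interp(np.mod(t, self.period), self.times, self.values)

    def scaled_to_mean(self, target_mean: float) -> "FlowWaveform":
        """Amplitude-scaled copy with the requested time-average flow."""
        m = self.mean
        if m == 0.0:
            raise ValueError("cannot rescale a zero-mean waveform")
        return FlowWaveform(self.period, self.times.copy(),
                            self.values * (target_mean / m))

    @classmethod
    def constant(cls, q_mlmin: float, period: float = 1.0) -> "FlowWaveform":
        t = np.array([0.0, period])
        return cls(period, t, np.array([q_mlmin, q_mlmin]))


class ConstitutiveLaw:
    """Thin-wall linear-elastic tube law at one cross-section.

    Relates transmural pressure changes to area changes about the reference
    area A_0 = pi r^2: dA/dp = 2 pi r^3 / (E h), so the area is strictly
    increasing in pressure.
    """

    def __init__(self, radius_mm: float, wall_mm: float, youngs_kpa: float):
        self.r = units.mm_to_m(radius_mm)
        self.h = units.mm_to_m(wall_mm)
        self.E = units.kpa_to_pa(youngs_kpa)
        self.reference_area = math.pi * self.r ** 2  # m^2

    @property
    def compliance_per_area(self) -> float:
        """dA/dp in m^2/Pa."""
        return 2.0 * math.pi * self.r ** 3 / (self.E * self.h)

    def area(self, p_pa: float, p_ref: float = 0.0) -> float:
        """Linearized area at transmural pressure p (Pa)."""
        return self.reference_area + self.compliance_per_area * (p_pa - p_ref)

    def wave_speed(self) -> float:
        """Moens-Korteweg pulse wave speed, m/s."""
        return math.sqrt(self.E * self.h / (2.0 * units.BLOOD_DENSITY * self.r))


# ---------------------------------------------------------------------------
# Lumped element laws (clinical-unit convenience wrappers)
# ---------------------------------------------------------------------------

def anastomosis_loss_coefficient(junction: AnastomosisJunction) -> float:
    """Quadratic loss coefficient K2 (SI: Pa per (m^3/s)^2) of the
    anastomosis: dp = K2 * q|q|."""
    a_a = junction.feeding_artery_area * 1e-6   # m^2
    a_v = junction.draining_vein_area * 1e-6
    theta = math.radians(junction.angle_deg)
    k = (ANASTOMOSIS_CV * (1.0 - math.cos(theta)) / a_v ** 2
         + ANASTOMOSIS_CA / a_a ** 2)
    return 0.5 * units.BLOOD_DENSITY * k


def anastomosis_pressure_drop(q_mlmin: float,
                              junction: AnastomosisJunction) -> float:
    """Pressure drop over the anastomosis (mmHg) at flow q (ml/min).

    Zero at zero flow, quadratic (superlinear) in flow, non-decreasing in
    the anastomosis angle and non-increasing in each area.
    """
    q = units.mlmin_to_m3s(q_mlmin)
    k2 = anastomosis_loss_coefficient(junction)
    return units.pa_to_mmhg(k2 * q * abs(q))


def stenosis_coefficients(insert: StenosisInsert) -> tuple[float, float, float]:
    """(R_viscous, K2_quadratic, L_inertance) of a stenosis insert in SI.

    dp = R_v q + K2 q|q| + L dq/dt. With A_s = A_0 the viscous term equals
    the Poiseuille drop of the straight reference tube and K2 vanishes.
    """
    a0 = insert.reference_area * 1e-6        # m^2
    a_s = insert.diseased_area * 1e-6
    ls = units.cm_to_m(insert.length)
    d0 = 2.0 * math.sqrt(a0 / math.pi)
    kv = 32.0 * (ls / d0) * (a0 / a_s) ** 2
    r_visc = kv * units.BLOOD_VISCOSITY / (a0 * d0)
    k2 = STENOSIS_KT * units.BLOOD_DENSITY / (2.0 * a0 ** 2) \
        * (a0 / a_s - 1.0) ** 2
    inertance = STENOSIS_KU * units.BLOOD_DENSITY * ls / a0
    return r_visc, k2, inertance


def stenosis_pressure_drop(q_mlmin: float, dqdt_mlmin_per_s: float,
                           insert: StenosisInsert) -> float:
    """Pressure drop over a stenosis (mmHg): viscous + quadratic + unsteady
    (+ constant offset, default 0)."""
    r_v, k2, inertance = stenosis_coefficients(insert)
    q = units.mlmin_to_m3s(q_mlmin)
    dqdt = units.mlmin_to_m3s(dqdt_mlmin_per_s)
    dp = r_v * q + k2 * q * abs(q) + inertance * dqdt
    return units.pa_to_mmhg(dp) + STENOSIS_OFFSET_MMHG


def windkessel_update(p_terminal: float, state: float, Z: float, R: float,
                      C: float, p_out: float, dt: float) -> tuple[float, float]:
    """One backward-Euler step of a three-element windkessel.

    Parameters are in clinical units (mmHg, mmHg.min/ml, ml/mmHg); ``state``
    is the pressure over the compliance, ``dt`` is in seconds. Returns
    (outflow ml/min, new state). In steady state the outflow is
    (p_terminal - p_out) / (Z + R).
    """
    if Z <= 0:
        raise ValueError("windkessel characteristic impedance must be > 0")
    dt_min = dt / 60.0
    r = max(R, 1e-12)
    denom = C / dt_min + 1.0 / Z + 1.0 / r
    state_new = (C / dt_min * state + p_terminal / Z + p_out / r) / denom
    q = (p_terminal - state_new) / Z
    return q, state_new


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class _AssembledModel:
    node_names: list[str]
    node_index: dict[str, int]
    n_nodes: int
    # element arrays (SI)
    elem_meta: list[tuple[str, int]]          # (segment name, element index)
    elem_prox: np.ndarray
    elem_dist: np.ndarray
    elem_R: np.ndarray
    elem_L: np.ndarray
    elem_K2: np.ndarray                        # quadratic loss coefficient
    node_C: np.ndarray
    # windkessels
    wk_nodes: np.ndarray
    wk_names: list[str]
    wk_Z: np.ndarray
    wk_R: np.ndarray
    wk_C: np.ndarray
    wk_pout: np.ndarray
    inflow_idx: int
    outlet_idx: Optional[int]
    outlet_pressure_pa: float


def _element_rlc(r_p_m: float, r_d_m: float, h_p_m: float, h_d_m: float,
                 e_pa: float, l_m: float) -> tuple[float, float, float]:
    mu, rho = units.BLOOD_VISCOSITY, units.BLOOD_DENSITY
    if abs(r_d_m - r_p_m) < 1e-12 * max(r_p_m, r_d_m):
        int_inv_r4 = l_m / r_p_m ** 4
        int_inv_r2 = l_m / r_p_m ** 2
    else:
        int_inv_r4 = l_m * (r_p_m ** -3 - r_d_m ** -3) / (3.0 * (r_d_m - r_p_m))
        int_inv_r2 = l_m / (r_p_m * r_d_m)
    resistance = 8.0 * mu / math.pi * int_inv_r4
    inertance = rho / math.pi * int_inv_r2
    # Simpson integration of dA/dp = 2 pi r^3 / (E h) along the element
    caps = []
    for f in (0.0, 0.5, 1.0):
        r = r_p_m + (r_d_m - r_p_m) * f
        h = h_p_m + (h_d_m - h_p_m) * f
        caps.append(2.0 * math.pi * r ** 3 / (e_pa * h))
    compliance = l_m * (caps[0] + 4.0 * caps[1] + caps[2]) / 6.0
    return resistance, inertance, compliance


def assemble(network: VascularNetwork,
             max_element_length: float = MAX_ELEMENT_LENGTH_CM) -> _AssembledModel:
    """Discretize the network and build the SI element/terminal arrays."""
    elem_meta: list[tuple[str, int]] = []
    prox: list[str] = []
    dist: list[str] = []
    e_r: list[float] = []
    e_l: list[float] = []
    e_k2: list[float] = []
    node_c: dict[str, float] = {}

    def _touch(node: str, dc: float = 0.0) -> None:
        node_c[node] = node_c.get(node, 0.0) + dc

    for seg in network.segments.values():
        for i, el in enumerate(discretize_segment(seg, max_element_length)):
            r, l, c = _element_rlc(
                units.mm_to_m(el.r_p), units.mm_to_m(el.r_d),
                units.mm_to_m(el.h_p), units.mm_to_m(el.h_d),
                units.kpa_to_pa(el.youngs_modulus), units.cm_to_m(el.length))
            elem_meta.append((seg.name, i))
            prox.append(el.proximal_node)
            dist.append(el.distal_node)
            e_r.append(r)
            e_l.append(l)
            e_k2.append(0.0)
            _touch(el.proximal_node, c / 2.0)
            _touch(el.distal_node, c / 2.0)

    for si, st in enumerate(network.stenoses):
        r_v, k2, inertance = stenosis_coefficients(st.insert)
        elem_meta.append((f"stenosis:{st.vessel}", si))
        prox.append(st.proximal_node)
        dist.append(st.distal_node)
        e_r.append(r_v)
        e_l.append(inertance)
        e_k2.append(k2)
        _touch(st.proximal_node)
        _touch(st.distal_node)

    if network.anastomosis is not None:
        network.refresh_anastomosis_areas()
        k2 = anastomosis_loss_coefficient(network.anastomosis)
        a_v = network.anastomosis.draining_vein_area * 1e-6
        inertance = units.BLOOD_DENSITY \
            * units.cm_to_m(ANASTOMOSIS_EFFECTIVE_LENGTH_CM) / a_v
        elem_meta.append(("anastomosis", 0))
        prox.append(network.anastomosis_artery_node)
        dist.append(network.anastomosis_vein_node)
        e_r.append(0.0)
        e_l.append(inertance)
        e_k2.append(k2)
        _touch(network.anastomosis_artery_node)
        _touch(network.anastomosis_vein_node)

    node_names = sorted(node_c)
    node_index = {n: i for i, n in enumerate(node_names)}

    wk_nodes, wk_names, wk_z, wk_r, wk_c, wk_pout = [], [], [], [], [], []
    for wk in network.terminals.values():
        if wk.node not in node_index:
            continue
        wk_nodes.append(node_index[wk.node])
        wk_names.append(wk.name or wk.node)
        wk_z.append(max(units.resistance_to_si(wk.Z), _WK_Z_FLOOR_SI))
        wk_r.append(max(units.resistance_to_si(wk.R), _WK_R_FLOOR_SI))
        wk_c.append(units.compliance_to_si(wk.C))
        wk_pout.append(units.mmhg_to_pa(wk.p_out))

    outlet_idx = (node_index[network.venous_outlet_node]
                  if network.venous_outlet_node in node_index else None)
    return _AssembledModel(
        node_names=node_names, node_index=node_index, n_nodes=len(node_names),
        elem_meta=elem_meta,
        elem_prox=np.array([node_index[n] for n in prox], dtype=int),
        elem_dist=np.array([node_index[n] for n in dist], dtype=int),
        elem_R=np.array(e_r), elem_L=np.array(e_l), elem_K2=np.array(e_k2),
        node_C=np.array([node_c[n] for n in node_names]),
        wk_nodes=np.array(wk_nodes, dtype=int), wk_names=wk_names,
        wk_Z=np.array(wk_z), wk_R=np.array(wk_r), wk_C=np.array(wk_c),
        wk_pout=np.array(wk_pout),
        inflow_idx=node_index[network.inflow_node],
        outlet_idx=outlet_idx,
        outlet_pressure_pa=units.mmhg_to_pa(network.venous_outlet_pressure))


# ---------------------------------------------------------------------------
# Solution container
# ---------------------------------------------------------------------------

@dataclass
class Solution:
    """Last-cycle periodic solution: per-node pressures (mmHg), per-element
    flows (ml/min), terminal outflows, and convergence metadata."""

    times: np.ndarray
    node_names: list[str]
    pressures: np.ndarray            # (n_nodes, nt) mmHg
    elem_meta: list[tuple[str, int]]
    flows: np.ndarray                # (n_elem, nt) ml/min
    wk_names: list[str]
    wk_flows: np.ndarray             # (n_wk, nt) ml/min
    inflow_mean: float               # ml/min
    cycles_run: int = 0
    periodicity_residual: float = float("nan")
    converged: bool = True
    _node_index: dict = field(default_factory=dict, repr=False)
    _elem_index: dict = field(default_factory=dict, repr=False)
    _mass_residual: Optional[float] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._node_index = {n: i for i, n in enumerate(self.node_names)}
        self._elem_index = {m: i for i, m in enumerate(self.elem_meta)}

    def pressure(self, node: str) -> np.ndarray:
        return self.pressures[self._node_index[node]]

    def mean_pressure(self, node: str) -> float:
        t, p = self.times, self.pressure(node)
        return float(np.trapezoid(p, t) / (t[-1] - t[0]))

    def _elem_for(self, segment: str, end: str) -> int:
        idx = [i for m, i in self.elem_meta if m == segment]
        if not idx:
            raise KeyError(f"no elements for segment {segment!r}")
        which = min(idx) if end == "proximal" else max(idx)
        return self._elem_index[(segment, which)]

    def segment_flow(self, segment: str, end: str = "proximal") -> np.ndarray:
        return self.flows[self._elem_for(segment, end)]

    def mean_segment_flow(self, segment: str, end: str = "proximal") -> float:
        t = self.times
        q = self.segment_flow(segment, end)
        return float(np.trapezoid(q, t) / (t[-1] - t[0]))

    def terminal_mean_outflows(self) -> dict[str, float]:
        t = self.times
        return {name: float(np.trapezoid(self.wk_flows[i], t) / (t[-1] - t[0]))
                for i, name in enumerate(self.wk_names)}

    @property
    def mass_residual(self) -> float:
        """Max over junction nodes of |cycle-mean net inflow| / mean inflow."""
        return self._mass_residual if self._mass_residual is not None \
            else float("nan")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SolverSettings:
    """Numerical settings for the pulse-wave solver.

    dt: time step (s); n_cycles: maximum cardiac cycles; ptol: cycle-to-cycle
    relative change in mean pressures accepted as periodic;
    max_element_length: 1D discretization cap (cm).
    """

    dt: float = 1.0e-3
    n_cycles: int = 20
    ptol: float = 0.005
    max_element_length: float = MAX_ELEMENT_LENGTH_CM

    def coarse(self) -> "SolverSettings":
        """Throughput-oriented settings for Monte-Carlo sweeps."""
        return SolverSettings(dt=5.0e-3, n_cycles=self.n_cycles,
                              ptol=self.ptol,
                              max_element_length=self.max_element_length)


def solve_steady(network: VascularNetwork, inflow_mlmin: float,
                 max_element_length: float = MAX_ELEMENT_LENGTH_CM,
                 model: Optional[_AssembledModel] = None,
                 picard_tol: float = 1e-10, max_iter: int = 80):
    """Zero-frequency (DC) solution of the network at a steady inflow.

    Returns (pressures mmHg by node name, flows ml/min by element, model).
    Used both as the mean-flow oracle in the linear limit and as the warm
    start for the time-dependent solver.
    """
    m = model or assemble(network, max_element_length)
    n, ne, nw = m.n_nodes, len(m.elem_meta), len(m.wk_nodes)
    ntot = n + ne + nw
    q_in = units.mlmin_to_m3s(inflow_mlmin)

    a = np.zeros((ntot, ntot))
    b = np.zeros(ntot)
    # node rows: sum of element flows + windkessel drains = source
    for e in range(ne):
        a[m.elem_prox[e], n + e] += 1.0   # flow leaves proximal node
        a[m.elem_dist[e], n + e] -= 1.0   # flow enters distal node
    for w in range(nw):
        i = m.wk_nodes[w]
        a[i, i] += 1.0 / m.wk_Z[w]
        a[i, n + ne + w] -= 1.0 / m.wk_Z[w]
    b[m.inflow_idx] += q_in
    # element rows
    for e in range(ne):
        a[n + e, m.elem_prox[e]] = -1.0
        a[n + e, m.elem_dist[e]] = 1.0
        a[n + e, n + e] = m.elem_R[e]
    # windkessel rows
    for w in range(nw):
        row = n + ne + w
        a[row, m.wk_nodes[w]] = -1.0 / m.wk_Z[w]
        a[row, row] = 1.0 / m.wk_Z[w] + 1.0 / m.wk_R[w]
        b[row] = m.wk_pout[w] / m.wk_R[w]
    if m.outlet_idx is not None:
        a[m.outlet_idx, :] = 0.0
        a[m.outlet_idx, m.outlet_idx] = 1.0
        b[m.outlet_idx] = m.outlet_pressure_pa

    nl = np.nonzero(m.elem_K2)[0]
    q_abs = np.zeros(ne)
    x = np.zeros(ntot)
    for _ in range(max_iter):
        for e in nl:
            a[n + e, n + e] = m.elem_R[e] + m.elem_K2[e] * q_abs[e]
        x = np.linalg.solve(a, b)
        q_new = np.abs(x[n:n + ne])
        if nl.size == 0 or np.allclose(q_new[nl], q_abs[nl],
                                       rtol=picard_tol, atol=1e-16):
            q_abs = q_new
            break
        q_abs = 0.5 * q_abs + 0.5 * q_new
    pressures = {name: units.pa_to_mmhg(x[i])
                 for name, i in m.node_index.items()}
    flows = {meta: units.m3s_to_mlmin(x[n + e])
             for e, meta in enumerate(m.elem_meta)}
    return pressures, flows, m, x


def simulate(network: VascularNetwork, inflow: FlowWaveform,
             n_cycles: Optional[int] = None, dt: Optional[float] = None,
             settings: Optional[SolverSettings] = None,
             init_state: Optional[np.ndarray] = None,
             raise_on_nonconvergence: bool = True) -> Solution:
    """Run the network to a periodic steady state under a periodic inflow.

    The state is initialized from the steady (DC) solution at the mean
    inflow unless ``init_state`` is given (e.g., a previous solution's final
    state, to warm-start Monte-Carlo sweeps). Convergence is declared when
    the cycle-to-cycle change in node mean pressures drops below
    ``settings.ptol`` (relative to the mean pressure scale); otherwise a
    ConvergenceError is raised (or the flag is set when
    ``raise_on_nonconvergence`` is false).
    """
    s = settings or SolverSettings()
    if dt is not None:
        s = SolverSettings(dt=dt, n_cycles=s.n_cycles, ptol=s.ptol,
                           max_element_length=s.max_element_length)
    if n_cycles is not None:
        s = SolverSettings(dt=s.dt, n_cycles=n_cycles, ptol=s.ptol,
                           max_element_length=s.max_element_length)

    _, _, m, x0 = solve_steady(network, inflow.mean,
                               s.max_element_length)
    n, ne, nw = m.n_nodes, len(m.elem_meta), len(m.wk_nodes)
    ntot = n + ne + nw
    x = x0 if init_state is None else init_state.copy()
    if x.shape != (ntot,):
        raise ValueError("init_state has wrong shape for this network")

    dt = s.dt
    nsteps = max(2, int(round(inflow.period / dt)))
    dt = inflow.period / nsteps
    t_steps = dt * np.arange(1, nsteps + 1)
    q_in_steps = units.mlmin_to_m3s(np.asarray(inflow(t_steps), dtype=float))

    # constant part of the backward-Euler matrix
    a = np.zeros((ntot, ntot))
    mdiag = np.zeros(ntot)
    mdiag[:n] = m.node_C / dt
    mdiag[n:n + ne] = m.elem_L / dt
    mdiag[n + ne:] = m.wk_C / dt
    for e in range(ne):
        a[m.elem_prox[e], n + e] += 1.0
        a[m.elem_dist[e], n + e] -= 1.0
        a[n + e, m.elem_prox[e]] = -1.0
        a[n + e, m.elem_dist[e]] = 1.0
        a[n + e, n + e] = mdiag[n + e] + m.elem_R[e]
    for w in range(nw):
        i, row = m.wk_nodes[w], n + ne + w
        a[i, i] += 1.0 / m.wk_Z[w]
        a[i, row] -= 1.0 / m.wk_Z[w]
        a[row, i] = -1.0 / m.wk_Z[w]
        a[row, row] = mdiag[row] + 1.0 / m.wk_Z[w] + 1.0 / m.wk_R[w]
    a[np.arange(n), np.arange(n)] += mdiag[:n]
    b_const = np.zeros(ntot)
    b_const[n + ne:] = m.wk_pout / m.wk_R
    if m.outlet_idx is not None:
        a[m.outlet_idx, :] = 0.0
        a[m.outlet_idx, m.outlet_idx] = 1.0
        mdiag[m.outlet_idx] = 0.0
        b_const[m.outlet_idx] = m.outlet_pressure_pa
    nl = np.nonzero(m.elem_K2)[0]

    p_hist = np.empty((n, nsteps))
    q_hist = np.empty((ne, nsteps))
    w_hist = np.empty((nw, nsteps))
    prev_means = None
    residual = float("inf")
    converged = False
    cycles = 0
    rhs = np.empty(ntot)
    for cyc in range(s.n_cycles):
        for k in range(nsteps):
            for e in nl:
                a[n + e, n + e] = mdiag[n + e] + m.elem_R[e] \
                    + m.elem_K2[e] * abs(x[n + e])
            np.multiply(mdiag, x, out=rhs)
            rhs += b_const
            rhs[m.inflow_idx] += q_in_steps[k]
            x = np.linalg.solve(a, rhs)
            p_hist[:, k] = x[:n]
            q_hist[:, k] = x[n:n + ne]
            w_hist[:, k] = x[n + ne:]
        cycles = cyc + 1
        means = p_hist.mean(axis=1)
        if prev_means is not None:
            scale = max(np.abs(means).max(), units.mmhg_to_pa(1.0))
            residual = float(np.abs(means - prev_means).max() / scale)
            if residual < s.ptol:
                converged = True
                break
        prev_means = means.copy()
    if not converged:
        msg = (f"no periodic steady state after {cycles} cycles "
               f"(residual {residual:.3e})")
        if raise_on_nonconvergence:
            raise ConvergenceError(msg)
        warnings.warn(msg)

    times = np.concatenate([[0.0], t_steps])
    pressures = units.pa_to_mmhg(
        np.concatenate([p_hist[:, -1:], p_hist], axis=1))
    flows = units.m3s_to_mlmin(
        np.concatenate([q_hist[:, -1:], q_hist], axis=1))
    wkp = np.concatenate([w_hist[:, -1:], w_hist], axis=1)
    p_at_wk = np.concatenate([p_hist[:, -1:], p_hist], axis=1)[m.wk_nodes] \
        if nw else np.empty((0, nsteps + 1))
    wk_flows = units.m3s_to_mlmin(
        (p_at_wk - wkp) / m.wk_Z[:, None]) if nw else np.empty((0, nsteps + 1))

    sol = Solution(times=times, node_names=m.node_names, pressures=pressures,
                   elem_meta=list(m.elem_meta), flows=flows,
                   wk_names=list(m.wk_names), wk_flows=wk_flows,
                   inflow_mean=inflow.mean, cycles_run=cycles,
                   periodicity_residual=residual, converged=converged)
    sol._mass_residual = _junction_mass_residual(m, sol)
    sol.final_state = x  # type: ignore[attr-defined]
    return sol


def _junction_mass_residual(m: _AssembledModel, sol: Solution) -> float:
    """Cycle-mean net flow imbalance at each node, relative to mean inflow."""
    t = sol.times
    span = t[-1] - t[0]
    qmean = np.trapezoid(sol.flows, t, axis=1) / span        # ml/min
    wmean = (np.trapezoid(sol.wk_flows, t, axis=1) / span
             if len(sol.wk_names) else np.empty(0))
    net = np.zeros(m.n_nodes)
    for e in range(len(m.elem_meta)):
        net[m.elem_prox[e]] -= qmean[e]
        net[m.elem_dist[e]] += qmean[e]
    for w in range(len(m.wk_nodes)):
        net[m.wk_nodes[w]] -= wmean[w]
    net[m.inflow_idx] += sol.inflow_mean
    if m.outlet_idx is not None:
        net[m.outlet_idx] = 0.0
    scale = abs(sol.inflow_mean) if sol.inflow_mean else 1.0
    return float(np.abs(net).max() / scale)


# ---------------------------------------------------------------------------
# Baroreflex cardiac-output iteration
# ---------------------------------------------------------------------------

@dataclass
class BaroreflexResult:
    cardiac_output: float        # ml/min
    mean_arch_pressure: float    # mmHg
    iterations: int              # extra simulations beyond the first
    solution: Solution
    relative_error: float


def baroreflex_iterate(network: VascularNetwork, inflow_shape: FlowWaveform,
                       target_mean_pressure: float, tol: float = 0.05,
                       arch_node: str = "n_arch",
                       settings: Optional[SolverSettings] = None,
                       co_init: Optional[float] = None,
                       max_iter: int = 15,
                       warm_state: Optional[np.ndarray] = None) -> BaroreflexResult:
    """Rescale cardiac output until the mean aortic-arch pressure is within
    ``tol`` (relative) of the target; only the waveform amplitude is scaled,
    its shape and period are preserved.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if target_mean_pressure <= 0:
        raise ValueError("target pressure must be positive")
    s = settings or SolverSettings()
    co = co_init if co_init is not None else inflow_shape.mean
    history: list[tuple[float, float]] = []
    sol = None
    state = warm_state
    for it in range(max_iter):
        sol = simulate(network, inflow_shape.scaled_to_mean(co), settings=s,
                       init_state=state)
        state = sol.final_state  # type: ignore[attr-defined]
        p = sol.mean_pressure(arch_node)
        err = abs(p - target_mean_pressure) / target_mean_pressure
        if err <= tol:
            return BaroreflexResult(cardiac_output=co, mean_arch_pressure=p,
                                    iterations=it, solution=sol,
                                    relative_error=err)
        history.append((co, p))
        if len(history) >= 2 and history[-1][1] != history[-2][1]:
            (c0, p0), (c1, p1) = history[-2], history[-1]
            co = c1 + (target_mean_pressure - p1) * (c1 - c0) / (p1 - p0)
        else:
            co = co * target_mean_pressure / p
        co = max(co, 1e-3)
    raise ConvergenceError(
        f"baroreflex did not converge within {max_iter} iterations "
        f"(last pressure {history[-1][1]:.1f} mmHg, "
        f"target {target_mean_pressure:.1f} mmHg)")
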