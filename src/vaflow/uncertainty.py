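"""Geometric Monte-Carlo uncertainty analysis of the flow prediction.

Only geometric inputs are varied: the diameters of the protocol stations in
the VA in-/outflow tract (uniform ±10% arterial, ±30% venous), a global
diameter factor scaling the non-measured parts of the generic geometry
(±10%), and — when a stenosis is modeled — its length (±2 cm, floored) and
healthy/diseased areas (±20%). Latin-hypercube sampling covers the joint
parameter space with exactly one sample per equal-probability stratum per
dimension; the default budget is 1000 samples per parameter. Each sample is
pushed through the postoperative simulation (with the cardiac-output
baroreflex loop) and the cycle-mean arm inflow is recorded; the prediction
interval is the empirical 25th-75th percentile band, compared with the
measured postoperative flow range by closed-interval overlap.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import qmc

from .network import (StenosisInsert, VascularNetwork,
                      apply_global_diameter_factor, insert_stenosis)
from .personalize import FlowRange
from .solver import (FlowWaveform, SolverSettings, baroreflex_iterate,
                     solve_steady, ConvergenceError)

ARTERIAL_DIAMETER_UNCERTAINTY = 0.10   # relative half-width
VENOUS_DIAMETER_UNCERTAINTY = 0.30
GLOBAL_FACTOR_UNCERTAINTY = 0.10
STENOSIS_LENGTH_HALF_WIDTH_CM = 2.0
STENOSIS_LENGTH_FLOOR_CM = 0.5
STENOSIS_AREA_UNCERTAINTY = 0.20
DEFAULT_SAMPLES_PER_PARAMETER = 1000


@dataclass
class UncertainParameter:
    """One uniformly distributed geometric parameter.

    ``half_width`` is relative (fraction of nominal) for kind 'relative' and
    absolute (same units as nominal) for kind 'absolute'; the support is
    symmetric about the nominal, floored at ``floor`` to stay physical.
    """

    name: str
    nominal: float
    half_width: float
    kind: str = "relative"            # "relative" | "absolute"
    floor: float = 1e-9
    target: tuple = ()                # how to apply (see _apply_row)

    def bounds(self) -> tuple[float, float]:
        hw = self.half_width * self.nominal if self.kind == "relative" \
            else self.half_width
        return (max(self.nominal - hw, self.floor), self.nominal + hw)


@dataclass
class MCResult:
    """Monte-Carlo output: the sampled parameter matrix, per-sample
    predicted arm inflow, and the 25th-75th percentile interval."""

    parameter_names: list[str]
    samples: np.ndarray                  # (N, k)
    arm_inflow: np.ndarray               # (N,) ml/min, NaN where failed
    p25: float
    p75: float
    seed: Optional[int]
    n_failed: int = 0
    cardiac_outputs: np.ndarray = field(default=None)  # type: ignore

    @property
    def interval(self) -> tuple[float, float]:
        return (self.p25, self.p75)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.p25 + self.p75)

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / max(len(self.arm_inflow), 1)


def build_uncertainty_spec(network: VascularNetwork) -> list[UncertainParameter]:
    """Uncertain geometric parameters of a personalized postoperative
    network: one per in-/outflow-tract station diameter (arterial ±10%,
    venous ±30%), the global diameter factor (±10%), plus length/areas for
    every modeled stenosis."""
    params: list[UncertainParameter] = []
    for label in network.uncertain_arterial_stations:
        slots = [s for s in network.stations[label] if s[0] in network.segments]
        if not slots:
            continue
        params.append(UncertainParameter(
            name=f"diam:{label}", nominal=network.get_station_radius(label),
            half_width=ARTERIAL_DIAMETER_UNCERTAINTY,
            target=("station", label)))
    for label in network.uncertain_venous_stations:
        slots = [s for s in network.stations[label] if s[0] in network.segments]
        if not slots:
            continue
        params.append(UncertainParameter(
            name=f"diam:{label}", nominal=network.get_station_radius(label),
            half_width=VENOUS_DIAMETER_UNCERTAINTY,
            target=("station", label)))
    params.append(UncertainParameter(
        name="global_diameter_factor", nominal=1.0,
        half_width=GLOBAL_FACTOR_UNCERTAINTY, target=("global_factor",)))
    for i, st in enumerate(network.stenoses):
        params.append(UncertainParameter(
            name=f"stenosis{i}:length", nominal=st.insert.length,
            half_width=STENOSIS_LENGTH_HALF_WIDTH_CM, kind="absolute",
            floor=STENOSIS_LENGTH_FLOOR_CM, target=("stenosis", i, "length")))
        params.append(UncertainParameter(
            name=f"stenosis{i}:A0", nominal=st.insert.reference_area,
            half_width=STENOSIS_AREA_UNCERTAINTY,
            target=("stenosis", i, "reference_area")))
        params.append(UncertainParameter(
            name=f"stenosis{i}:As", nominal=st.insert.diseased_area,
            half_width=STENOSIS_AREA_UNCERTAINTY,
            target=("stenosis", i, "diseased_area")))
    return params


def lhs_sample(spec: Sequence[UncertainParameter],
               samples_per_parameter: int = DEFAULT_SAMPLES_PER_PARAMETER,
               seed: Optional[int] = None) -> np.ndarray:
    """Latin-hypercube sample matrix with N = samples_per_parameter * k rows:
    per dimension, each of the N equal-probability strata holds exactly one
    sample. Reproducible under a fixed seed."""
    k = len(spec)
    if k < 1:
        raise ValueError("need at least one uncertain parameter")
    n = samples_per_parameter * k
    unit = qmc.LatinHypercube(d=k, seed=seed).random(n)
    lo = np.array([p.bounds()[0] for p in spec])
    hi = np.array([p.bounds()[1] for p in spec])
    return lo + unit * (hi - lo)  # degenerate (zero-width) bounds allowed


def _apply_row(network: VascularNetwork, spec: Sequence[UncertainParameter],
               row: np.ndarray) -> VascularNetwork:
    net = copy.deepcopy(network)
    f_d = 1.0
    for p, v in zip(spec, row):
        if p.target[0] == "station":
            net.set_station_radius(p.target[1], float(v))
        elif p.target[0] == "global_factor":
            f_d = float(v)
        elif p.target[0] == "stenosis":
            _, i, attr = p.target
            setattr(net.stenoses[i].insert, attr, float(v))
    for st in net.stenoses:
        # independent area sampling can invert the narrowing; keep it physical
        st.insert.diseased_area = min(st.insert.diseased_area,
                                      st.insert.reference_area)
    if f_d != 1.0:
        net = apply_global_diameter_factor(net, f_d)
    net.refresh_anastomosis_areas()
    return net


def _steady_baroreflex(network: VascularNetwork, target_pressure: float,
                       co_init: float, tol: float = 0.05,
                       max_iter: int = 15) -> tuple[float, float]:
    """Cardiac-output loop on the DC network; returns (CO, arm inflow)."""
    co = co_init
    hist: list[tuple[float, float]] = []
    for _ in range(max_iter):
        pressures, flows, _, _ = solve_steady(network, co)
        p = pressures["n_arch"]
        if abs(p - target_pressure) / target_pressure <= tol:
            return co, flows[("brachial_prox", 0)]
        hist.append((co, p))
        if len(hist) >= 2 and hist[-1][1] != hist[-2][1]:
            (c0, p0), (c1, p1) = hist[-2], hist[-1]
            co = c1 + (target_pressure - p1) * (c1 - c0) / (p1 - p0)
        else:
            co = co * target_pressure / p
        co = max(co, 1e-3)
    raise ConvergenceError("steady baroreflex did not converge")


def run_monte_carlo(network: VascularNetwork,
                    spec: Sequence[UncertainParameter],
                    samples: np.ndarray,
                    inflow_shape: FlowWaveform,
                    target_mean_pressure: float,
                    settings: Optional[SolverSettings] = None,
                    mode: str = "pulsatile",
                    seed: Optional[int] = None) -> MCResult:
    """Propagate every sampled geometry through the postoperative
    simulation with the baroreflex loop and collect the cycle-mean arm
    inflow (proximal brachial artery).

    ``mode='pulsatile'`` runs the full pulse-wave solver per sample
    (warm-started from the nominal converged solution); ``mode='steady'``
    uses the DC limit of the same network, a fast surrogate whose mean flows
    match the pulsatile cycle-means to within the quadratic-loss
    pulsatility correction. Failed samples are excluded and counted.
    """
    s = settings or SolverSettings()
    nominal = baroreflex_iterate(network, inflow_shape, target_mean_pressure,
                                 settings=s)
    co0 = nominal.cardiac_output
    warm = nominal.solution.final_state  # type: ignore[attr-defined]

    n = samples.shape[0]
    inflows = np.full(n, np.nan)
    cos = np.full(n, np.nan)
    n_failed = 0
    for i in range(n):
        net_i = _apply_row(network, spec, samples[i])
        try:
            if mode == "steady":
                co, q = _steady_baroreflex(net_i, target_mean_pressure, co0)
            else:
                res = baroreflex_iterate(net_i, inflow_shape,
                                         target_mean_pressure, settings=s,
                                         co_init=co0, warm_state=warm)
                co = res.cardiac_output
                q = res.solution.mean_segment_flow("brachial_prox", "proximal")
            if not np.isfinite(q):
                raise ConvergenceError("non-finite arm inflow")
            inflows[i] = q
            cos[i] = co
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    ok = np.isfinite(inflows)
    if not ok.any():
        raise ConvergenceError("all Monte-Carlo samples failed")
    p25, p75 = np.percentile(inflows[ok], [25.0, 75.0])
    return MCResult(parameter_names=[p.name for p in spec],
                    samples=samples, arm_inflow=inflows,
                    p25=float(p25), p75=float(p75), seed=seed,
                    n_failed=n_failed, cardiac_outputs=cos)


def assess_overlap(model_interval: tuple[float, float],
                   measured: FlowRange) -> bool:
    """True iff the model's percentile interval and the measured flow range
    intersect (closed intervals; touching endpoints count as overlap)."""
    lo, hi = model_interval
    if lo > hi:
        raise ValueError("model interval must satisfy p25 <= p75")
    return lo <= measured.high and measured.low <= hi


def rerun_with_stenosis(network: VascularNetwork,
                        stenosis_placements: Sequence[tuple[str, float,
                                                            StenosisInsert]],
                        inflow_shape: FlowWaveform,
                        target_mean_pressure: float,
                        samples_per_parameter: int = DEFAULT_SAMPLES_PER_PARAMETER,
                        seed: Optional[int] = None,
                        settings: Optional[SolverSettings] = None,
                        mode: str = "pulsatile") -> tuple[MCResult, MCResult]:
    """Prediction intervals before and after augmenting the model with
    identified stenoses; the 'after' analysis adds the stenosis length/area
    parameters to the uncertainty spec."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]
    spec0 = build_uncertainty_spec(network)
    before = run_monte_carlo(
        network, spec0,
        lhs_sample(spec0, samples_per_parameter, seed=seeds[0]),
        inflow_shape, target_mean_pressure, settings=settings, mode=mode,
        seed=seeds[0])
    net_st = network
    for vessel, position, insert in stenosis_placements:
        net_st = insert_stenosis(net_st, vessel, position, insert)
    spec1 = build_uncertainty_spec(net_st)
    after = run_monte_carlo(
        net_st, spec1,
        lhs_sample(spec1, samples_per_parameter, seed=seeds[1]),
        inflow_shape, target_mean_pressure, settings=settings, mode=mode,
        seed=seeds[1])
    return before, after
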