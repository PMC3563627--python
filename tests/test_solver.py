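"""Pulse-wave solver physics: closed-form oracles and conservation laws."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vaflow import units
from vaflow.network import (AnastomosisJunction, StenosisInsert,
                            VAConfiguration, VascularNetwork, VesselSegment,
                            WindkesselTerminal, build_generic_arm_network,
                            insert_stenosis, stenosis_from_severity)
from vaflow.solver import (FlowWaveform, SolverSettings,
                           anastomosis_pressure_drop, baroreflex_iterate,
                           simulate, solve_steady, stenosis_pressure_drop,
                           windkessel_update)
from vaflow.synthetic import generate_inflow_waveform


def _single_tube(r_mm=2.0, L_cm=20.0, E_kpa=1e6, h_mm=None, Z=0.01, R=1.0,
                 C=0.0):
    net = VascularNetwork(inflow_node="in")
    kw = {} if h_mm is None else {"h_p": h_mm, "h_d": h_mm}
    net.segments["tube"] = VesselSegment(
        name="tube", role="artery", proximal_node="in", distal_node="out",
        r_p=r_mm, r_d=r_mm, length=L_cm, youngs_modulus=E_kpa, **kw)
    net.terminals["out"] = WindkesselTerminal(node="out", Z=Z, R=R, C=C,
                                              p_out=10.0)
    return net


class TestTubeOracles:
    def test_poiseuille_pressure_drop(self):
        """Steady flow through a rigid uniform tube reproduces
        dp = 8 mu L Q / (pi r^4) to within 1%."""
        r_mm, L_cm, q = 2.0, 20.0, 300.0
        net = _single_tube(r_mm, L_cm)
        p, _, _, _ = solve_steady(net, q)
        dp = p["in"] - p["out"]
        q_si = units.mlmin_to_m3s(q)
        oracle = units.pa_to_mmhg(
            8 * units.BLOOD_VISCOSITY * units.cm_to_m(L_cm) * q_si
            / (math.pi * units.mm_to_m(r_mm) ** 4))
        assert dp == pytest.approx(oracle, rel=0.01)

    def test_moens_korteweg_wave_speed(self):
        """A small pulse on a compliant tube with a reflection-free
        termination travels at c = sqrt(E h / (2 rho r)) within 5%."""
        r_mm, h_mm, e_kpa, L_cm = 3.0, 0.3, 400.0, 80.0
        c_mk = units.moens_korteweg_speed(r_mm, h_mm, e_kpa)
        area = math.pi * units.mm_to_m(r_mm) ** 2
        z_char = units.resistance_to_clinical(units.BLOOD_DENSITY * c_mk / area)
        net = _single_tube(r_mm, L_cm, e_kpa, h_mm, Z=z_char, R=1e-6)
        t = np.linspace(0, 1.0, 2001)
        q = 50.0 + 30.0 * np.exp(-(((t - 0.1) / 0.02) ** 2))
        q[-1] = q[0]
        sol = simulate(net, FlowWaveform(1.0, t, q),
                       settings=SolverSettings(dt=2.5e-4, n_cycles=8,
                                               max_element_length=1.0))

        def peak_time(node):
            p = sol.pressure(node)
            i = int(np.argmax(p))
            num = p[i - 1] - p[i + 1]
            den = p[i - 1] - 2 * p[i] + p[i + 1]
            return sol.times[i] + 0.5 * num / den * (sol.times[1] - sol.times[0])

        c_meas = 0.40 / (peak_time("tube:60") - peak_time("tube:20"))
        assert c_meas == pytest.approx(c_mk, rel=0.05)

    def test_zero_inflow_static_equilibrium(self):
        net = _single_tube(C=0.01)
        sol = simulate(net, FlowWaveform.constant(0.0),
                       settings=SolverSettings(dt=2e-3, n_cycles=15))
        assert np.allclose(sol.pressures, 10.0, atol=1e-6)
        assert np.allclose(sol.flows, 0.0, atol=1e-6)


class TestWindkessel:
    def test_steady_limit(self):
        q, state = 0.0, 10.0
        for _ in range(40000):
            q, state = windkessel_update(100.0, state, Z=0.2, R=0.8, C=0.01,
                                         p_out=10.0, dt=1e-3)
        assert q == pytest.approx((100.0 - 10.0) / (0.2 + 0.8), rel=1e-4)

    def test_zero_compliance_is_instantaneous(self):
        for p_t in (40.0, 100.0, 250.0):
            q, _ = windkessel_update(p_t, 0.0, Z=0.3, R=0.7, C=0.0,
                                     p_out=10.0, dt=1e-3)
            assert q == pytest.approx((p_t - 10.0) / 1.0, rel=1e-12)

    def test_step_response_time_constant(self):
        """Settling after a pressure step follows the closed-form ODE time
        constant tau = C (Z R / (Z + R)); with Z >> R this approaches R C
        (within 2%)."""
        Z, R, C = 50.0, 1.0, 0.02
        dt = 1e-3
        n = 12000
        state = 10.0
        qs = []
        for _ in range(n):
            q, state = windkessel_update(100.0, state, Z, R, C, 10.0, dt)
            qs.append(q)
        qs = np.array(qs)
        tau_oracle = C * (Z * R / (Z + R)) * 60.0
        assert tau_oracle == pytest.approx(R * C * 60.0, rel=0.02)
        t = dt * np.arange(1, n + 1)
        resid = np.abs(qs - qs[-1])
        sl = np.polyfit(t[200:1200], np.log(resid[200:1200]), 1)[0]
        assert -1.0 / sl == pytest.approx(tau_oracle, rel=0.02)


class TestAnastomosisLaw:
    JUNCTION = dict(feeding_artery_area=4.0, draining_vein_area=8.0)

    def test_zero_flow_zero_drop(self):
        j = AnastomosisJunction(**self.JUNCTION, angle_deg=45.0)
        assert anastomosis_pressure_drop(0.0, j) == 0.0

    @given(q=st.floats(10.0, 2000.0))
    def test_superlinear_in_flow(self, q):
        j = AnastomosisJunction(**self.JUNCTION, angle_deg=45.0)
        ratio = anastomosis_pressure_drop(2 * q, j) / \
            anastomosis_pressure_drop(q, j)
        assert ratio > 2.0

    def test_monotone_in_angle_and_areas(self):
        j45 = AnastomosisJunction(**self.JUNCTION, angle_deg=45.0)
        j60 = AnastomosisJunction(**self.JUNCTION, angle_deg=60.0)
        assert anastomosis_pressure_drop(500.0, j60) >= \
            anastomosis_pressure_drop(500.0, j45)
        bigger_vein = AnastomosisJunction(feeding_artery_area=4.0,
                                          draining_vein_area=12.0,
                                          angle_deg=45.0)
        bigger_artery = AnastomosisJunction(feeding_artery_area=6.0,
                                            draining_vein_area=8.0,
                                            angle_deg=45.0)
        base = anastomosis_pressure_drop(500.0, j45)
        assert anastomosis_pressure_drop(500.0, bigger_vein) <= base
        assert anastomosis_pressure_drop(500.0, bigger_artery) <= base


class TestStenosisLaw:
    def test_zero_flow_zero_drop(self):
        ins = StenosisInsert(3.5, 4.0, 1.0)
        assert stenosis_pressure_drop(0.0, 0.0, ins) == 0.0

    def test_degenerate_equals_viscous_tube(self):
        """With A_s = A_0 the drop reduces to the straight-segment Poiseuille
        term within 1%."""
        r_mm, L_cm, q = 1.5, 3.5, 250.0
        area = math.pi * r_mm ** 2
        ins = StenosisInsert(L_cm, area, area)
        q_si = units.mlmin_to_m3s(q)
        poiseuille = units.pa_to_mmhg(
            8 * units.BLOOD_VISCOSITY * units.cm_to_m(L_cm) * q_si
            / (math.pi * units.mm_to_m(r_mm) ** 4))
        assert stenosis_pressure_drop(q, 0.0, ins) == pytest.approx(
            poiseuille, rel=0.01)

    def test_quadratic_dominance_at_large_flow(self):
        """For a severe narrowing at large steady flow the drop approaches
        the quadratic-only term Kt rho/2 (A_0/A_s - 1)^2 q^2 / A_0^2."""
        ins = StenosisInsert(2.0, 8.0, 1.6)
        q = 12000.0
        q_si = units.mlmin_to_m3s(q)
        a0 = ins.reference_area * 1e-6
        quad = units.pa_to_mmhg(
            1.52 * units.BLOOD_DENSITY / (2 * a0 ** 2)
            * (a0 / (ins.diseased_area * 1e-6) - 1.0) ** 2 * q_si ** 2)
        assert stenosis_pressure_drop(q, 0.0, ins) == pytest.approx(
            quad, rel=0.05)


class TestBaroreflex:
    def test_within_tolerance_returns_unchanged(self):
        net = _single_tube(C=0.005)
        wf = generate_inflow_waveform(cardiac_output=200.0)
        sol = simulate(net, wf, settings=SolverSettings(dt=2e-3, n_cycles=15))
        target = sol.mean_pressure("in")
        res = baroreflex_iterate(net, wf, target, tol=0.05, arch_node="in",
                                 settings=SolverSettings(dt=2e-3, n_cycles=15))
        assert res.iterations == 0
        assert res.cardiac_output == pytest.approx(200.0)

    def test_resistive_network_recovers_analytic_co(self):
        """On a purely resistive network p_mean = p_out + R_tot * CO, so the
        loop should find CO = (p* - p_out) / R_tot."""
        net = _single_tube(r_mm=3.0, L_cm=5.0, Z=0.05, R=0.95, C=0.0)
        r_tube = units.resistance_to_clinical(
            8 * units.BLOOD_VISCOSITY * units.cm_to_m(5.0)
            / (math.pi * units.mm_to_m(3.0) ** 4))
        r_tot = r_tube + 1.0
        target = 90.0
        co_oracle = (target - 10.0) / r_tot
        res = baroreflex_iterate(net, FlowWaveform.constant(50.0), target,
                                 tol=0.01, arch_node="in",
                                 settings=SolverSettings(dt=2e-3, n_cycles=15))
        assert res.cardiac_output == pytest.approx(co_oracle, rel=0.01)

    def test_postoperative_co_not_below_preoperative(self, clean_patient,
                                                     clean_case,
                                                     coarse_settings):
        wf = generate_inflow_waveform()
        res = baroreflex_iterate(clean_case.network_post, wf,
                                 clean_case.target_mean_pressure,
                                 settings=coarse_settings)
        assert res.cardiac_output >= 5100.0 - 1e-6


class TestConservationAndConvergence:
    def test_flow_conservation_and_outlet_pressure(self, clean_case,
                                                   coarse_settings):
        """Cycle-averaged inflow equals the summed terminal outflows (plus
        the venous outlet drain) within 0.5%, junction mass balance is below
        1e-3, and the prescribed venous outlet holds 10 mmHg."""
        wf = generate_inflow_waveform()
        for net in (clean_case.network_pre, clean_case.network_post):
            sol = simulate(net, wf, settings=coarse_settings)
            assert sol.mass_residual < 1e-3
            outflows = sum(sol.terminal_mean_outflows().values())
            if net.venous_outlet_node is not None:
                outflows += sol.mean_segment_flow("subclavian_v", "distal")
                assert sol.mean_pressure(net.venous_outlet_node) == \
                    pytest.approx(10.0, abs=1e-6)
            assert outflows == pytest.approx(sol.inflow_mean, rel=0.005)

    def test_time_step_convergence(self, clean_case):
        """Halving dt changes the predicted mean arm inflow by < 1%."""
        wf = generate_inflow_waveform()
        q = {}
        for dt in (5e-3, 2.5e-3):
            sol = simulate(clean_case.network_post, wf,
                           settings=SolverSettings(dt=dt, n_cycles=30))
            q[dt] = sol.mean_segment_flow("brachial_prox", "proximal")
        assert q[2.5e-3] == pytest.approx(q[5e-3], rel=0.01)

    def test_linear_limit_matches_dc_circuit(self, clean_case,
                                             coarse_settings):
        """With a vanishing pulse the cycle-mean flows reduce to the
        resistive-compliant DC solution within 1%."""
        net = clean_case.network_post
        co = 5400.0
        t = np.linspace(0, 1.0, 201)
        q = co * (1.0 + 0.01 * np.sin(2 * np.pi * t))
        q[-1] = q[0]
        sol = simulate(net, FlowWaveform(1.0, t, q), settings=coarse_settings)
        _, flows, _, _ = solve_steady(net, co)
        for seg in ("brachial_prox", "radial_prox", "cephalic_forearm_d"):
            assert sol.mean_segment_flow(seg, "proximal") == pytest.approx(
                flows[(seg, 0)], rel=0.01)

    def test_stenosis_severity_monotonically_reduces_va_flow(self, clean_case,
                                                             coarse_settings):
        """Tightening an inflow-tract stenosis strictly decreases the
        predicted access flow."""
        wf = generate_inflow_waveform()
        base = clean_case.network_post
        ref_area = math.pi * base.segments["radial_prox"].radius_at(5.75) ** 2
        flows = []
        for sev in (0.2, 0.5, 0.75):
            net = insert_stenosis(base, "radial_prox", 4.0,
                                  stenosis_from_severity(sev, ref_area, 3.5))
            res = baroreflex_iterate(net, wf, clean_case.target_mean_pressure,
                                     settings=coarse_settings)
            flows.append(res.solution.mean_segment_flow("brachial_prox",
                                                        "proximal"))
        assert flows[0] > flows[1] > flows[2]
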