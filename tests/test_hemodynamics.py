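"""Poiseuille network flow, apparent viscosity, phase separation and
hematocrit propagation."""

import numpy as np
import pytest

from tumoroxy.core import (ARTERIAL_ROOT, MMHG_TO_PA, VENOUS_ROOT,
                           HemoParams, VesselNetwork)
from tumoroxy.fixtures import make_bifurcation, make_random_network
from tumoroxy.hemodynamics import (FlowState, phase_separation_split,
                                   propagate_hematocrit, relative_viscosity,
                                   segment_conductance, solve_hemodynamics,
                                   solve_pressures)


class TestViscosity:
    def test_plasma_limit(self):
        # the in-vivo law retains the endothelial-surface-layer factor at
        # H=0; the in-vitro (glass tube) law reduces to pure plasma
        r = np.array([3.0, 10.0, 40.0])
        d = 2 * r
        np.testing.assert_allclose(relative_viscosity(r, 0.0, "invivo"),
                                   (d / (d - 1.1)) ** 2, rtol=1e-12)
        np.testing.assert_allclose(relative_viscosity(r, 0.0, "invitro"),
                                   1.0, rtol=1e-12)

    def test_interior_minimum_and_rise_at_large_radius(self):
        r = np.linspace(2.0, 300.0, 400)
        eta = relative_viscosity(r, 0.45)
        imin = int(np.argmin(eta))
        assert 0 < imin < len(r) - 1          # interior minimum
        assert eta[-1] > eta[imin]            # rises again for large r
        assert eta[0] > 3 * eta[imin]         # steep capillary branch

    def test_continuity_in_H(self):
        H = np.linspace(0.0, 0.8, 200)
        eta = relative_viscosity(4.0, H)
        assert np.all(np.abs(np.diff(eta)) < 0.5)
        assert np.all(np.diff(eta) > 0)       # monotone in H


class TestConductance:
    def test_r4_and_length_scaling(self):
        g = segment_conductance(2.0, 100.0, 1.2)
        assert np.isclose(segment_conductance(4.0, 100.0, 1.2), 16 * g)
        assert np.isclose(segment_conductance(2.0, 50.0, 1.2), 2 * g)

    def test_unit_audit(self):
        # pi*256/(8*1.2e-3 Pa s*100) in um^3/(s Pa), times Pa/mmHg
        expect = np.pi * 256 / (8 * 1.2e-3 * 100) * MMHG_TO_PA
        assert np.isclose(segment_conductance(4.0, 100.0, 1.2), expect)

    def test_zero_length_raises(self):
        with pytest.raises(ValueError):
            segment_conductance(4.0, 0.0, 1.2)


class TestPressureSolve:
    def test_two_node_closed_form(self):
        net = VesselNetwork()
        a = net.add_node([0, 0, 0], role=ARTERIAL_ROOT)
        b = net.add_node([200, 0, 0], role=VENOUS_ROOT)
        net.add_segment(a, b, 10.0, H=0.45)
        hp = HemoParams()
        flow = solve_pressures(net, hp)
        eta = hp.eta_plasma * relative_viscosity(10.0, 0.45)
        g = segment_conductance(10.0, 200.0, eta)
        dp = hp.root_pressure(10.0, ARTERIAL_ROOT) \
            - hp.root_pressure(10.0, VENOUS_ROOT)
        assert np.isclose(flow.q[0], g * dp, rtol=1e-12)

    def test_symmetric_bifurcation_splits_equally(self):
        net = make_bifurcation(r1=4.0, r2=4.0)
        flow = solve_pressures(net, HemoParams())
        assert np.isclose(flow.q[1], flow.q[2], rtol=1e-10)
        assert np.isclose(flow.q[0], flow.q[1] + flow.q[2], rtol=1e-10)

    def test_matches_dense_lu_oracle(self):
        net = make_random_network(40, seed=5)
        hp = HemoParams()
        flow = solve_pressures(net, hp)
        # independent dense assembly
        n = net.n_nodes
        eta = hp.eta_plasma * relative_viscosity(net.r_tilde, net.H)
        g = np.pi * net.r_tilde ** 4 * MMHG_TO_PA / (8e-3 * eta * net.l)
        A = np.zeros((n, n))
        rhs = np.zeros(n)
        for s in range(net.n_segments):
            i, j = net.a[s], net.b[s]
            A[i, i] += g[s]
            A[j, j] += g[s]
            A[i, j] -= g[s]
            A[j, i] -= g[s]
        for u in range(n):
            if net.role[u] != 0:
                A[u, :] = 0.0
                A[u, u] = 1.0
                r_u = max(net.r[s] for s in range(net.n_segments)
                          if u in (net.a[s], net.b[s]))
                rhs[u] = hp.root_pressure(r_u, int(net.role[u]))
        p = np.linalg.solve(A, rhs)
        np.testing.assert_allclose(flow.pressure, p, rtol=1e-8)

    def test_mass_conservation_at_interior_nodes(self, small_net,
                                                 small_config):
        flow = solve_pressures(small_net, small_config.hemo)
        div = np.zeros(small_net.n_nodes)
        np.add.at(div, small_net.a, -flow.q)
        np.add.at(div, small_net.b, flow.q)
        interior = small_net.role == 0
        scale = np.abs(flow.q).max()
        assert np.abs(div[interior]).max() < 1e-8 * scale

    def test_rootless_component_raises(self):
        net = make_random_network(10, seed=2)
        c = net.add_node([10, 10, 10])
        d = net.add_node([20, 10, 10])
        net.add_segment(c, d, 3.0)
        with pytest.raises(ValueError, match="no root"):
            solve_pressures(net, HemoParams())


class TestPhaseSeparation:
    def test_symmetric_split_is_even(self):
        h1, h2 = phase_separation_split(2.0, 0.45, 10.0, 1.0, 8.0, 1.0, 8.0)
        assert np.isclose(h1, 0.45) and np.isclose(h2, 0.45)

    @pytest.mark.parametrize("law", ["pries1990", "invivo2005"])
    @pytest.mark.parametrize("q1,d1,d2,H", [
        (0.3, 6.0, 8.0, 0.45), (0.7, 8.0, 6.0, 0.2), (0.5, 5.0, 12.0, 0.6),
        (0.95, 7.0, 7.0, 0.45)])
    def test_rbc_flux_conservation(self, law, q1, d1, d2, H):
        q2 = 1.0 - q1
        h1, h2 = phase_separation_split(1.0, H, 10.0, q1, d1, q2, d2, law)
        assert np.isclose(h1 * q1 + h2 * q2, H, atol=1e-12)

    def test_faster_branch_gets_richer_blood(self):
        h_fast, h_slow = phase_separation_split(
            1.0, 0.45, 10.0, 0.8, 8.0, 0.2, 8.0)
        assert h_fast > h_slow

    def test_zero_parent_flow_convention(self):
        h1, h2 = phase_separation_split(0.0, 0.45, 10.0, 0.0, 8.0, 0.0, 8.0)
        assert h1 == h2 == 0.45


class TestHematocritPropagation:
    def _merge_fixture(self):
        net = VesselNetwork()
        a = net.add_node([0, 100, 0])
        b = net.add_node([0, -100, 0])
        m = net.add_node([100, 0, 0])
        c = net.add_node([300, 0, 0], role=VENOUS_ROOT)
        net.add_segment(a, m, 5.0, H=0.3)
        net.add_segment(b, m, 5.0, H=0.6)
        net.add_segment(m, c, 6.0, H=0.0)
        return net

    def test_merge_mixing_arithmetic(self):
        net = self._merge_fixture()
        flow = FlowState(pressure=np.array([3.0, 3.0, 2.0, 1.0]),
                         q=np.array([2.0, 1.0, 3.0]),
                         f=np.zeros(3), eta=np.ones(3))
        H = propagate_hematocrit(net, flow, HemoParams())
        assert np.isclose(H[2], (2 * 0.3 + 1 * 0.6) / 3.0)   # 0.4

    def test_straight_chain_keeps_inlet_hematocrit(self):
        net = VesselNetwork()
        ids = net.add_nodes([[100.0 * i, 0, 0] for i in range(5)])
        net.role[ids[0]] = ARTERIAL_ROOT
        net.role[ids[-1]] = VENOUS_ROOT
        net.add_segments(ids[:-1], ids[1:], 5.0, H=0.1)
        hp = HemoParams()
        flow = solve_pressures(net, hp)
        H = propagate_hematocrit(net, flow, hp)
        np.testing.assert_allclose(H, hp.H_bc)

    def test_network_rbc_conservation(self, small_net, small_config):
        flow = solve_pressures(small_net, small_config.hemo)
        net = small_net
        rbc_in = rbc_out = 0.0
        for s in range(net.n_segments):
            for node, sign in ((net.a[s], 1.0), (net.b[s], -1.0)):
                if net.role[node] == 0:
                    continue
                qs = sign * flow.q[s]   # out of the root into the segment
                if qs > 0:
                    rbc_in += qs * net.H[s]
                else:
                    rbc_out += -qs * net.H[s]
        assert np.isclose(rbc_in, rbc_out, rtol=2e-3)


class TestSelfConsistentSolve:
    def test_converges_and_flags(self):
        net = make_bifurcation(r1=3.0, r2=6.0)
        flow = solve_hemodynamics(net, HemoParams())
        assert flow.converged

    def test_fixed_point_independent_of_damping(self):
        from dataclasses import replace
        H_final = []
        for relax in (0.5, 0.3):
            net = make_bifurcation(r1=3.0, r2=6.0)
            solve_hemodynamics(net, replace(HemoParams(), relax_H=relax))
            H_final.append(net.H.copy())
        np.testing.assert_allclose(H_final[0], H_final[1], atol=2e-4)

    def test_uniform_compression_reduces_total_perfusion(
            self, small_net, small_config):
        from tumoroxy.observables import perfusion
        hp = small_config.hemo
        L3 = small_config.L ** 3
        base = perfusion(small_net, solve_pressures(small_net, hp), L3)
        squeezed = small_net.copy()
        squeezed.r_tilde = 0.8 * squeezed.r
        comp = perfusion(squeezed, solve_pressures(squeezed, hp), L3)
        assert comp["rBF"] < base["rBF"]


# -------------------------------------------------- property-based checks
from hypothesis import given, settings, strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(q1=st.floats(0.05, 0.95), d1=st.floats(4.0, 20.0),
       d2=st.floats(4.0, 20.0), H=st.floats(0.05, 0.8),
       dp=st.floats(6.0, 40.0))
def test_phase_separation_conserves_rbc_flux_property(q1, d1, d2, H, dp):
    h1, h2 = phase_separation_split(1.0, H, dp, q1, d1, 1.0 - q1, d2)
    assert 0.0 <= h1 <= 0.99 + 1e-12 and 0.0 <= h2 <= 0.99 + 1e-12
    assert h1 * q1 + h2 * (1.0 - q1) == pytest.approx(H, abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(r=st.floats(1.5, 200.0), H=st.floats(0.0, 0.85))
def test_viscosity_positive_and_finite_property(r, H):
    eta = float(relative_viscosity(r, H))
    assert np.isfinite(eta) and eta > 0.9
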