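"""Poiseuille/Starling flow and the nodal pressure solver."""

import dataclasses
import math

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from tumorperf import hemodynamics as hd
from tumorperf import rheology
from tumorperf.config import SimulationConfig, SolverConfig
from tumorperf.coupling import build_pruned_network
from tumorperf.fixtures import diamond_loop, single_vessel
from tumorperf.units import MMHG_PA, lp_cgs_to_si


class TestPoiseuille:
    def test_zero_pressure_drop(self):
        assert hd.poiseuille_flow(12e-6, 20e-6, 0.0, 2e-3) == 0.0

    def test_parent_vessel_reference_flow(self):
        # D = 28 um, L = 2 mm, dP = 1950 Pa, mu = 0.0031 Pa s
        q = hd.poiseuille_flow(28e-6, 2e-3, 1950.0, 0.0031)
        assert q == pytest.approx(4.744767653056365e-12, rel=1e-12)
        # within 5% of the tabulated reference 4.87e-3 mm^3/s
        assert abs(q * 1e9 - 4.87e-3) / 4.87e-3 < 0.05

    def test_quartic_diameter_scaling(self):
        q1 = hd.poiseuille_flow(10e-6, 1e-3, 100.0, 2e-3)
        q2 = hd.poiseuille_flow(20e-6, 1e-3, 100.0, 2e-3)
        assert q2 / q1 == pytest.approx(16.0)

    def test_signed_with_pressure_drop(self):
        assert hd.poiseuille_flow(10e-6, 1e-3, -50.0, 2e-3) < 0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hd.poiseuille_flow(-1e-6, 1e-3, 10.0, 2e-3)


class TestStarling:
    def test_equilibrium_gives_zero_flux(self):
        sigma, dpi = 0.9, 1000.0
        q = hd.starling_flow(12e-6, 20e-6, pb_mean=500.0 + sigma * dpi,
                             pi_mean=500.0, lp=1e-11, sigma=sigma,
                             oncotic_difference=dpi)
        assert q == pytest.approx(0.0, abs=1e-30)

    def test_tumor_segment_hand_value(self):
        # D = 12 um, L = 20 um, Pb = 2660 Pa, Pi = 500 Pa, tumor wall
        lp = lp_cgs_to_si(2.8e-7)
        q = hd.starling_flow(12e-6, 20e-6, 2660.0, 500.0, lp, 0.82,
                             5.0 * MMHG_PA)
        assert q == pytest.approx(2.5547825485902363e-17, rel=1e-9)

    def test_reabsorption_sign(self):
        q = hd.starling_flow(12e-6, 20e-6, pb_mean=1000.0, pi_mean=900.0,
                             lp=1e-11, sigma=1.0,
                             oncotic_difference=2000.0)
        assert q < 0


class TestWallShear:
    def test_zero_flow(self):
        assert hd.wall_shear(12e-6, 0.0, 2e-3) == 0.0

    def test_cubic_diameter_scaling(self):
        t1 = hd.wall_shear(12e-6, 1e-12, 2e-3)
        t2 = hd.wall_shear(6e-6, 1e-12, 2e-3)
        assert t2 / t1 == pytest.approx(8.0)

    def test_parent_vessel_hand_value(self):
        t = hd.wall_shear(28e-6, 4.87e-12, 0.0031)
        assert t == pytest.approx(7.005137538945609, rel=1e-9)


class TestNodalSolver:
    def test_two_equal_segments_in_series(self, config):
        net = single_vessel(2)
        state = hd.solve_nodal_pressures(net, config.tissue, config.solver,
                                         leakage=False)
        assert net.nodes[1].pressure == pytest.approx(2327.5)
        assert state.inlet_flow == pytest.approx(state.outlet_flow)

    def test_symmetric_diamond_splits_evenly(self, config):
        net = diamond_loop()
        state = hd.solve_nodal_pressures(net, config.tissue, config.solver,
                                         leakage=False)
        q = {sid: abs(net.segments[sid].flow) for sid in net.segments}
        assert q[0] == pytest.approx(q[1], rel=1e-12)
        assert q[0] == pytest.approx(state.inlet_flow / 2, rel=1e-12)

    def test_leaky_vessel_global_mass_balance(self, config):
        net = single_vessel(10)
        state = hd.solve_nodal_pressures(net, config.tissue, config.solver,
                                         pi_field=np.zeros((100, 100)),
                                         leakage=True)
        assert hd.mass_balance_residual(state) < 1e-8

    def test_matches_dense_direct_solve(self, config):
        """Independent oracle: assemble the same resistor network with
        leakage as pressure-dependent sinks and solve it densely."""
        net = single_vessel(10)
        state = hd.solve_nodal_pressures(net, config.tissue, config.solver,
                                         pi_field=np.zeros((100, 100)),
                                         leakage=True)
        nodes = list(net.nodes)
        idx = {nid: i for i, nid in enumerate(nodes)}
        n = len(nodes)
        a = np.zeros((n, n))
        b = np.zeros(n)
        props = config.tissue.normal
        for seg in net.segments.values():
            g = math.pi * seg.diameter ** 4 / (128 * seg.viscosity
                                               * seg.length)
            kt = props.lp * math.pi * seg.diameter * seg.length
            c = props.oncotic_drop
            i, j = idx[seg.node_a], idx[seg.node_b]
            for me, you in ((i, j), (j, i)):
                a[me, me] += g + kt / 4
                a[me, you] -= g - kt / 4
                b[me] += kt * c / 2
        for nid in nodes:
            if net.nodes[nid].is_boundary:
                i = idx[nid]
                a[i, :] = 0.0
                a[i, i] = 1.0
                b[i] = 3325.0 if net.nodes[nid].role == "inlet" else 1330.0
        exact = np.linalg.solve(a, b)
        mine = np.array([net.nodes[nid].pressure for nid in nodes])
        assert np.max(np.abs(mine - exact)) / np.max(np.abs(exact)) < 1e-8

    def test_sor_and_direct_agree_on_loop_fixture(self):
        """SOR and the direct factorization give the same resistor-network
        solution on a small parent-plus-loops fixture."""
        from tumorperf.vessel_graph import Node, Segment, make_parent_vessel

        cfg = SimulationConfig()
        h = 1e-4
        net = make_parent_vessel(20, 2e-3)
        nid, sid = 100, 100
        # two capillary loops tapping different parent rows
        for j_lo, j_hi in ((3, 9), (10, 17)):
            chain = [j_lo]
            for k in range(4):
                net.add_node(Node(nid, (k + 1) * h + h / 2, (j_lo + k) * h))
                chain.append(nid)
                nid += 1
            chain.append(j_hi)
            for a, b in zip(chain, chain[1:]):
                net.add_segment(Segment(sid, a, b, diameter=12e-6, length=h))
                sid += 1
        rheology.update_network_viscosity(net, cfg.viscosity)
        direct = hd.solve_nodal_pressures(
            net.copy(), cfg.tissue,
            dataclasses.replace(cfg.solver, network_method="direct"),
            leakage=False)
        sor = hd.solve_nodal_pressures(
            net.copy(), cfg.tissue,
            dataclasses.replace(cfg.solver, network_method="sor", tol=1e-12),
            leakage=False)
        err = (np.max(np.abs(direct.pressures - sor.pressures))
               / np.max(np.abs(direct.pressures)))
        assert err < 1e-8

    def test_solution_invariant_under_node_relabeling(self, config):
        net = diamond_loop()
        hd.solve_nodal_pressures(net, config.tissue, config.solver,
                                 leakage=False)
        ref = {nid: net.nodes[nid].pressure for nid in net.nodes}
        relabeled = diamond_loop()
        mapping = {0: 10, 1: 31, 2: 22, 3: 43}
        renamed = type(relabeled)()
        for nid, node in relabeled.nodes.items():
            node = dataclasses.replace(node, id=mapping[nid])
            renamed.add_node(node)
        for sid, seg in sorted(relabeled.segments.items(), reverse=True):
            seg = dataclasses.replace(seg, node_a=mapping[seg.node_a],
                                      node_b=mapping[seg.node_b])
            renamed.add_segment(seg)
        hd.solve_nodal_pressures(renamed, config.tissue, config.solver,
                                 leakage=False)
        for old, new in mapping.items():
            assert renamed.nodes[new].pressure == pytest.approx(
                ref[old], rel=1e-10)

    def test_nodal_residuals_small(self, config):
        cfg = SimulationConfig(seed=4)
        net = build_pruned_network(cfg)
        rheology.update_network_viscosity(net, cfg.viscosity)
        state = hd.solve_nodal_pressures(net, cfg.tissue, cfg.solver,
                                         pi_field=np.zeros((100, 100)),
                                         leakage=True)
        scale = max(abs(state.inlet_flow), abs(state.outlet_flow))
        assert np.max(np.abs(state.residuals)) / scale < 1e-6
        assert hd.mass_balance_residual(state) < 1e-6

    def test_sor_independent_of_initialization(self, config):
        """Starting the relaxation from 0 or from the outlet pressure
        changes the iteration count only, not the converged state."""
        solver = dataclasses.replace(config.solver, network_method="sor",
                                     tol=1e-12)
        a = diamond_loop()
        hd.solve_nodal_pressures(a, config.tissue, solver, leakage=False,
                                 x0=np.zeros(4))
        b = diamond_loop()
        hd.solve_nodal_pressures(b, config.tissue, solver, leakage=False,
                                 x0=np.full(4, 1330.0))
        for nid in a.nodes:
            assert a.nodes[nid].pressure == pytest.approx(
                b.nodes[nid].pressure, rel=1e-9)

    def test_missing_viscosity_raises(self, config):
        net = diamond_loop()
        net.segments[2].viscosity = math.nan
        with pytest.raises(hd.FlowSolverError):
            hd.solve_nodal_pressures(net, config.tissue, config.solver)
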