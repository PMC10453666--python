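"""Finite-volume transport on the tree graph: stencils, conservation, CFL."""

import math

import numpy as np
import pytest

from coroperf.fixtures import (
    analytic_advection_case,
    fig3_graph,
    random_tree_graph,
    straight_line_graph,
)
from coroperf.tree_transport import (
    BIFURCATION,
    CFLError,
    REGULAR,
    ROOT,
    TERMINAL,
    InflowProfile,
    discretize_tree,
    inflow_value,
    map_terminals_to_cells,
    step_bifurcation,
    step_regular,
    step_terminal,
)


def dense_operator(graph, dt):
    """Independent dense one-step operator assembled edge by edge.

    For each edge the mass flux A*(v*C_up - D*(C_down - C_up)/dx) is
    credited downstream and debited upstream, scaled by the node volumes;
    terminal nodes additionally lose their advective outflow A*v*C to the
    microcirculation.
    """
    n = graph.n_nodes
    K = np.zeros((n, n))
    for e in range(len(graph.src)):
        s, d = graph.src[e], graph.dst[e]
        a, h, v = graph.area[e], graph.dx[e], graph.vel[e]
        D = graph.diffusion
        K[d, s] += a * (v + D / h)
        K[d, d] -= a * D / h
        K[s, s] -= a * (v + D / h)
        K[s, d] += a * D / h
    for t_idx, node in enumerate(graph.terminal_nodes):
        K[node, node] -= graph.term_outflow[t_idx]
    return np.eye(n) + dt * K / graph.volume[:, None]


class TestInflowProfile:
    def test_peak_at_t_peak(self):
        prof = InflowProfile(sigma=6.0, t_peak=25.0)
        ts = np.linspace(0, 100, 2001)
        vals = [inflow_value(t, prof) for t in ts]
        assert ts[int(np.argmax(vals))] == pytest.approx(25.0, abs=0.06)

    def test_maximum_value_closed_form(self):
        prof = InflowProfile(sigma=6.0, t_peak=25.0)
        assert inflow_value(25.0, prof) == pytest.approx(
            1.0 / (6.0 * math.sqrt(2 * math.pi))
        )

    def test_recirculation_shifts_additively(self):
        prof = InflowProfile()
        for t in (0.0, 10.0, 25.0):
            assert inflow_value(t, prof, x_t=0.3) == pytest.approx(
                inflow_value(t, prof) + 0.3
            )

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            InflowProfile(sigma=0.0)


class TestFig3Graph:
    def test_node_types_and_adjacency(self):
        g = fig3_graph()
        assert list(g.ntype) == [ROOT, REGULAR, BIFURCATION, TERMINAL, TERMINAL]
        assert g.neighbors(2) == [1, 3, 4]
        assert g.neighbors(0) == [1]
        assert g.neighbors(3) == [2]

    def test_inconsistent_flows_rejected(self):
        with pytest.raises(ValueError):
            fig3_graph(flow_split=1.5)

    def test_symmetric_daughters_stay_symmetric(self):
        g = fig3_graph(radii=(0.2, 0.1, 0.1), flow_split=0.5)
        g.C = np.array([1.0, 0.5, 0.2, 0.1, 0.1])
        dt = 0.5 * g.cfl_dt()
        for _ in range(10):
            g.step(dt)
        assert g.C[3] == pytest.approx(g.C[4], rel=1e-14)

    def test_one_step_matches_dense_operator(self):
        g = fig3_graph()
        rng = np.random.default_rng(0)
        g.C = rng.random(5)
        M = dense_operator(g, dt := 0.5 * g.cfl_dt())
        expected = M @ g.C
        g.step(dt)
        assert np.allclose(g.C, expected, rtol=1e-12, atol=1e-15)


class TestStepKernels:
    def test_unit_cfl_advection_shifts_one_node(self):
        g = straight_line_graph(10.0, 41, v=2.0, diffusion=0.0)
        x = g.pos[:, 0]
        g.C = np.exp(-0.5 * ((x - 3.0) / 0.8) ** 2)
        dt = g.cfl_dt()  # unit Courant
        before = g.C.copy()
        g.step(dt)
        # every node downstream of the root takes its upstream
        # neighbour's value (the terminal's own content flows out)
        assert np.allclose(g.C[1:], before[:-1], rtol=0, atol=1e-15)

    def test_uniform_field_unchanged_by_diffusion(self):
        g = straight_line_graph(10.0, 21, v=0.0, diffusion=0.01)
        g.C = np.full(21, 0.7)
        g.step(0.9 * g.cfl_dt())
        assert np.allclose(g.C, 0.7, rtol=1e-14)

    def test_single_node_kernels_match_graph_step(self):
        g = fig3_graph()
        rng = np.random.default_rng(3)
        C = rng.random(5)
        g.C = C.copy()
        dt = 0.5 * g.cfl_dt()
        g.step(dt)
        assert step_regular(g, 1, C, dt) == pytest.approx(g.C[1], rel=1e-13)
        assert step_bifurcation(g, 2, C, dt) == pytest.approx(g.C[2], rel=1e-13)

    def test_regular_stencil_printed_form(self):
        """On a uniform line the flux-form update equals the textbook
        upwind stencil C1 + dt*(D(C2-2C1+C0)/dx^2 - v(C1-C0)/dx)."""
        g = straight_line_graph(5.0, 11, v=1.0, diffusion=0.01)
        rng = np.random.default_rng(5)
        C = rng.random(11)
        dt = 0.4 * g.cfl_dt()
        dx = g.dx[0]
        i = 5
        expected = C[i] + dt * (
            g.diffusion * (C[i + 1] - 2 * C[i] + C[i - 1]) / dx**2
            - 1.0 * (C[i] - C[i - 1]) / dx
        )
        assert step_regular(g, i, C, dt) == pytest.approx(expected, rel=1e-13)

    def test_terminal_one_way_valve(self):
        g = fig3_graph()
        C = np.array([0.0, 0.0, 0.0, 0.5, 0.5])
        # C3 == Ce -> no exchange ; C3 < Ce -> no exchange either
        for ce in (0.5, 0.9):
            _, leaked = step_terminal(g, 3, C, ce, dt=1e-4, permeability=1.0)
            assert leaked == 0.0

    def test_terminal_explicit_euler_leak(self):
        """P=1/s, C=1, Ce=0, no advection/diffusion: C drops to 0.9 in
        dt=0.1 and the leaked mass is 0.1 * node volume."""
        g = straight_line_graph(1.0, 5, v=0.0, diffusion=0.0)
        C = np.zeros(5)
        C[-1] = 1.0
        c_new, leaked = step_terminal(g, 4, C, 0.0, dt=0.1, permeability=1.0)
        assert c_new == pytest.approx(0.9)
        assert leaked == pytest.approx(0.1 * g.volume[4])

    def test_cfl_violation_raises(self):
        g = straight_line_graph(10.0, 21, v=2.0, diffusion=0.0)
        with pytest.raises(CFLError):
            g.step(10.0 * g.cfl_dt())
        with pytest.raises(CFLError):
            step_regular(g, 5, g.C, 10.0 * g.cfl_dt())


class TestOperatorOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_graphs_match_dense_operator(self, seed):
        rng = np.random.default_rng(seed)
        g = random_tree_graph(rng, max_nodes=100)
        g.C = rng.random(g.n_nodes)
        dt = 0.5 * g.cfl_dt()
        expected = dense_operator(g, dt) @ g.C
        g.step(dt)
        err = np.abs(g.C - expected).max() / np.abs(expected).max()
        assert err < 1e-12


class TestConservationAndPositivity:
    def test_budget_identity_without_inflow_or_leak(self):
        """Interior transport conserves mass exactly: the only change in
        total tree mass is the tracked terminal washout."""
        rng = np.random.default_rng(8)
        g = random_tree_graph(rng, max_nodes=60)
        g.C = rng.random(g.n_nodes)
        m0 = g.total_mass()
        dt = 0.9 * g.cfl_dt()
        out = 0.0
        for _ in range(200):
            out += g.step(dt)["outflow_mass"]
            assert abs(g.total_mass() + out - m0) < 1e-10 * m0

    def test_mass_strictly_conserved_without_advection(self):
        """Pure diffusion (v = 0 everywhere): mass conserved to 1e-10."""
        g = straight_line_graph(10.0, 41, v=0.0, diffusion=0.01)
        rng = np.random.default_rng(8)
        g.C = rng.random(g.n_nodes)
        m0 = g.total_mass()
        dt = 0.9 * g.cfl_dt()
        for _ in range(200):
            g.step(dt)
            assert abs(g.total_mass() - m0) < 1e-10 * m0

    def test_nonnegativity_under_cfl(self):
        rng = np.random.default_rng(9)
        g = random_tree_graph(rng, max_nodes=80)
        g.C = rng.random(g.n_nodes)
        dt = 0.9 * g.cfl_dt()
        for _ in range(300):
            g.step(dt)
            assert (g.C >= -1e-15).all()

    def test_inflow_mass_accounting(self):
        g = straight_line_graph(10.0, 21, v=2.0, diffusion=0.0)
        dt = 0.5 * g.cfl_dt()
        budget = g.step(dt, inflow=1.0)
        assert budget["inflow_mass"] == pytest.approx(
            g.root_area[0] * g.root_vel[0] * 1.0 * dt
        )
        assert budget["outflow_mass"] == 0.0  # nothing at the leaf yet
        assert g.total_mass() == pytest.approx(budget["inflow_mass"], rel=1e-12)


class TestAdvectionConvergence:
    def test_first_order_in_dx(self):
        """L1 error of upwind advection halves (within 20%) when dx halves."""
        errors = []
        for n in (81, 161):
            g, exact = analytic_advection_case(length=20.0, v=2.0, sigma0=1.5, n_nodes=n)
            dx = g.dx[0]
            dt = 0.4 * dx / 2.0  # fixed Courant number
            t_final = 3.0
            steps = int(round(t_final / dt))
            for _ in range(steps):
                g.step(dt)
            err = np.abs(g.C[1:-1] - exact(steps * dt)[1:-1]).sum() * dx
            errors.append(err)
        ratio = errors[0] / errors[1]
        assert 1.6 < ratio < 2.4

    def test_peak_travels_at_advection_speed(self):
        g, exact = analytic_advection_case(length=20.0, v=2.0, sigma0=1.5, n_nodes=161)
        x = g.pos[:, 0]
        dt = 0.9 * g.cfl_dt()
        steps = int(round(2.0 / dt))
        for _ in range(steps):
            g.step(dt)
        peak = x[np.argmax(g.C)]
        assert peak == pytest.approx(5.0 + 2.0 * steps * dt, abs=0.3)


class TestDiscretization:
    def test_single_segment_node_count_and_types(self, domain):
        """A straight 1 mm segment at dx=0.25 gives 5 nodes:
        root, three regular, one terminal."""
        from coroperf.cco import CCOParams, ArterialTree
        from coroperf.hemodynamics import solve_flow

        p = CCOParams(n_term=1, seed=0)
        tree = ArterialTree(p, region="x")
        tree.prox = [np.array([0.0, 0.0])]
        tree.dist = [np.array([1.0, 0.0])]
        tree.parent, tree.left, tree.right, tree.nterm = [-1], [-1], [-1], [1]
        tree.rescale_radii()
        g = discretize_tree(tree, solve_flow(tree), dx=0.25)
        assert g.n_nodes == 5
        assert list(g.ntype) == [ROOT, REGULAR, REGULAR, REGULAR, TERMINAL]

    def test_node_count_matches_independent_traversal(self, small_tree, small_flow):
        g = discretize_tree(small_tree, small_flow, dx=0.25)
        lengths = small_tree.lengths()
        intervals = np.maximum(1, np.ceil(lengths / 0.25).astype(int))
        # nodes: one per interval end per segment, plus the single tree inlet
        assert g.n_nodes == intervals.sum() + 1
        assert len(g.src) == intervals.sum()

    def test_degrees_by_node_type(self, small_tree, small_flow):
        g = discretize_tree(small_tree, small_flow, dx=0.25)
        deg = g.degree()
        for t, d in ((ROOT, 1), (REGULAR, 2), (BIFURCATION, 3), (TERMINAL, 1)):
            assert (deg[g.ntype == t] == d).all()

    def test_terminal_cell_mapping_is_one_to_one(self, small_tree, small_flow, domain):
        g = discretize_tree(small_tree, small_flow, dx=0.25)
        map_terminals_to_cells(g, domain)
        cells = [tuple(c) for c in g.term_cell]
        assert len(cells) == len(set(cells))
        assert all(domain.mask[ix, iy] for ix, iy in cells)

    def test_dx_larger_than_segment_warns(self, small_tree, small_flow):
        with pytest.warns(UserWarning):
            discretize_tree(small_tree, small_flow, dx=5.0)
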