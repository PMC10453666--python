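"""Deterministic small-instance fixtures for the numerical kernels.

Every transport kernel can be exercised without running tree generation:
the five-node toy graph (root - regular - bifurcation - two terminals),
straight single-segment lines with a closed-form pure-advection solution,
a symmetric two-level arterial tree, and tiny fully-masked tissue grids.
Construction is seed-free and deterministic.
"""

from __future__ import annotations

import math

import numpy as np

from .cco import ArterialTree, CCOParams
from .domain import REGION_NONE, MyocardialDomain
from .tree_transport import (
    BIFURCATION,
    REGULAR,
    ROOT,
    TERMINAL,
    TransportGraph,
)


def fig3_graph(
    radii: tuple[float, float, float] = (0.2, 0.15, 0.12),
    v_parent: float = 10.0,
    flow_split: float = 0.5,
    dx: float = 0.25,
    diffusion: float = 1.0e-2,
) -> TransportGraph:
    """Five-node toy graph: root 0 - regular 1 - bifurcation 2 - terminals 3, 4.

    ``radii`` are (parent, daughter a, daughter b); daughter velocities are
    derived from the parent flow and ``flow_split`` so that volumetric flow
    is conserved at the bifurcation (A_p v_p = A_3 v_3 + A_4 v_4).
    """
    rp, r3, r4 = radii
    if min(radii) <= 0:
        raise ValueError("radii must be positive")
    if not (0.0 < flow_split < 1.0):
        raise ValueError("flow_split must lie in (0, 1)")
    ap, a3, a4 = (math.pi * r * r for r in radii)
    q = ap * v_parent
    v3 = flow_split * q / a3
    v4 = (1.0 - flow_split) * q / a4
    if abs(a3 * v3 + a4 * v4 - q) > 1e-9 * q:
        raise ValueError("daughter flows do not sum to the parent flow")
    pos = np.array(
        [[0.0, 0.0], [dx, 0.0], [2 * dx, 0.0], [3 * dx, dx], [3 * dx, -dx]]
    )
    return TransportGraph(
        pos=pos,
        radius=np.array([rp, rp, rp, r3, r4]),
        ntype=np.array([ROOT, REGULAR, BIFURCATION, TERMINAL, TERMINAL], dtype=np.int8),
        src=np.array([0, 1, 2, 2], dtype=np.int64),
        dst=np.array([1, 2, 3, 4], dtype=np.int64),
        area=np.array([ap, ap, a3, a4]),
        dx=np.full(4, dx),
        vel=np.array([v_parent, v_parent, v3, v4]),
        diffusion=diffusion,
        root_nodes=np.array([0], dtype=np.int64),
        root_area=np.array([ap]),
        root_vel=np.array([v_parent]),
        node_segment=np.zeros(5, dtype=np.int64),
    )


def straight_line_graph(
    length: float,
    n_nodes: int,
    v: float,
    radius: float = 0.1,
    diffusion: float = 0.0,
) -> TransportGraph:
    """A single straight vessel discretized into ``n_nodes`` nodes."""
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    x = np.linspace(0.0, length, n_nodes)
    pos = np.column_stack([x, np.zeros(n_nodes)])
    a = math.pi * radius * radius
    ntype = np.full(n_nodes, REGULAR, dtype=np.int8)
    ntype[0] = ROOT
    ntype[-1] = TERMINAL
    e = n_nodes - 1
    return TransportGraph(
        pos=pos,
        radius=np.full(n_nodes, radius),
        ntype=ntype,
        src=np.arange(e, dtype=np.int64),
        dst=np.arange(1, n_nodes, dtype=np.int64),
        area=np.full(e, a),
        dx=np.full(e, length / e),
        vel=np.full(e, v),
        diffusion=diffusion,
        root_nodes=np.array([0], dtype=np.int64),
        root_area=np.array([a]),
        root_vel=np.array([v]),
        node_segment=np.zeros(n_nodes, dtype=np.int64),
    )


def gaussian_pulse(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def analytic_advection_case(
    length: float = 20.0,
    v: float = 2.0,
    sigma0: float = 1.5,
    n_nodes: int = 81,
):
    """Straight line with a Gaussian pulse and its exact pure-advection solution.

    Returns ``(graph, exact)`` with ``exact(t)`` the translated Gaussian
    sampled at the node positions (D = 0, pulse far from both ends).
    """
    if v <= 0:
        raise ValueError("advection velocity must be positive")
    graph = straight_line_graph(length, n_nodes, v, diffusion=0.0)
    x = graph.pos[:, 0]
    x0 = length / 4.0

    def exact(t: float) -> np.ndarray:
        return gaussian_pulse(x, x0 + v * t, sigma0)

    graph.C = exact(0.0)
    return graph, exact


def symmetric_two_level_tree(
    params: CCOParams | None = None,
    trunk: float = 2.0,
    branch: float = 1.5,
) -> ArterialTree:
    """Root segment splitting into two mirror-image daughters.

    With identical daughters the bifurcation law forces
    r_parent = 2**(1/gamma) * r_daughter.
    """
    params = params or CCOParams(n_term=2, seed=0)
    tree = ArterialTree(params, region="fixture")
    a = np.array([0.0, 0.0])
    b = np.array([trunk, 0.0])
    c1 = b + np.array([branch, branch]) / math.sqrt(2.0)
    c2 = b + np.array([branch, -branch]) / math.sqrt(2.0)
    tree.prox = [a, b.copy(), b.copy()]
    tree.dist = [b.copy(), c1, c2]
    tree.parent = [-1, 0, 0]
    tree.left = [1, -1, -1]
    tree.right = [2, -1, -1]
    tree.nterm = [2, 1, 1]
    tree.rescale_radii()
    return tree


def micro_domain(n: int = 10, cell_size: float = 0.25) -> MyocardialDomain:
    """Fully-masked square micro-grid (reflective everywhere) for budget tests."""
    dom = MyocardialDomain(
        grid_shape=(n, n),
        cell_size=cell_size,
        mask=np.ones((n, n), dtype=bool),
        perfusion_region=np.zeros((n, n), dtype=np.int8),
        inner_radius=1e-6,
        outer_radius=n * cell_size,
        center=(n * cell_size / 2.0, n * cell_size / 2.0),
        angular_splits=((0.0, 2.1), (2.1, 4.2), (4.2, 2 * math.pi)),
    )
    return dom


def random_tree_graph(
    rng: np.random.Generator,
    max_nodes: int = 100,
    diffusion: float = 1.0e-2,
) -> TransportGraph:
    """Random small tree-shaped transport graph with conserved flows.

    Used to cross-check the vectorized step against an independently
    assembled operator.  Flows at bifurcations split randomly but
    conserve volume exactly; radii shrink downstream.
    """
    pos = [np.zeros(2)]
    radius = [0.3]
    ntype = [ROOT]
    src, dst, area, dxs, vel = [], [], [], [], []
    flows = {0: math.pi * radius[0] ** 2 * 5.0}
    frontier = [0]
    while len(pos) < max_nodes and frontier:
        i = frontier.pop(0)
        q = flows[i]
        branch = rng.random() < 0.3 and len(pos) + 2 <= max_nodes
        if branch:
            split = rng.uniform(0.3, 0.7)
            qs = [split * q, (1 - split) * q]
            if i != 0:
                ntype[i] = BIFURCATION
        else:
            qs = [q]
        for qc in qs:
            r = radius[i] * rng.uniform(0.7, 1.0)
            a = math.pi * r * r
            j = len(pos)
            pos.append(pos[i] + rng.normal(0, 1, 2))
            radius.append(r)
            ntype.append(REGULAR)
            src.append(i)
            dst.append(j)
            area.append(a)
            dxs.append(rng.uniform(0.2, 0.4))
            vel.append(qc / a)
            flows[j] = qc
            frontier.append(j)
    # leaves become terminals
    ntype = np.asarray(ntype, dtype=np.int8)
    has_out = np.zeros(len(pos), dtype=bool)
    has_out[np.asarray(src, dtype=int)] = True
    ntype[(~has_out) & (np.arange(len(pos)) != 0)] = TERMINAL
    a0 = math.pi * radius[0] ** 2
    return TransportGraph(
        pos=np.asarray(pos),
        radius=np.asarray(radius),
        ntype=ntype,
        src=np.asarray(src, dtype=np.int64),
        dst=np.asarray(dst, dtype=np.int64),
        area=np.asarray(area),
        dx=np.asarray(dxs),
        vel=np.asarray(vel),
        diffusion=diffusion,
        root_nodes=np.array([0], dtype=np.int64),
        root_area=np.array([a0]),
        root_vel=np.array([5.0]),
        node_segment=np.zeros(len(pos), dtype=np.int64),
    )
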