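"""Finite-volume contrast-agent transport on a discretized arterial tree.

Every segment of a grown tree is split into near-``dx`` intervals, giving
a node graph with four node types: root (tree inlet), regular (two
neighbours), bifurcation (three neighbours) and terminal (one neighbour,
coupled to a tissue cell).  Intravascular concentration is advanced by an
explicit-Euler, first-order-upwind finite-volume step written in flux
form: every edge carries the advective + diffusive mass flux

    F_e = A_e * ( v_e * C_upwind - D * (C_down - C_up) / dx_e ),

which is added to the downstream node and subtracted from the upstream
one, so interior mass is conserved to machine precision by construction.
At bifurcations the daughter faces enter with their own cross-sectional
areas, i.e. the update is the area-weighted conservative form of the
upwind stencil (for a single daughter of equal radius it reduces to the
regular-node stencil).

Contrast enters at the root nodes as an imposed convective-diffusive
influx A*v*Q(t), with Q(t) a Gaussian bolus (mean t_peak, width sigma)
plus the recirculation return X(t).  Terminals leak one-way into their
mapped tissue cell at rate P*(C - Ce) when C > Ce, and the advective
flux A*v*C continues through each terminal into the unmodeled
microcirculation (upwind in-minus-out at the leaf node): without this
washout, contrast carried by the terminal outflows would pile up at the
leaves and the recirculation feedback would diverge.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cco import ArterialTree
from .hemodynamics import FlowSolution

ROOT, REGULAR, BIFURCATION, TERMINAL = 0, 1, 2, 3
NODE_TYPE_NAMES = ("root", "regular", "bifurcation", "terminal")


class CFLError(RuntimeError):
    """Raised when a step would violate the explicit-Euler stability bound."""


@dataclass(frozen=True)
class InflowProfile:
    """Gaussian contrast bolus imposed at the tree roots.

    sigma : width (standard deviation) of the infusion, s.
    t_peak : time of the bolus peak, s.
    """

    sigma: float = 6.0
    t_peak: float = 25.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def inflow_value(t: float, profile: InflowProfile, x_t: float = 0.0) -> float:
    """Root inflow concentration: normalized Gaussian at t plus recirculation X."""
    if t < 0:
        raise ValueError("time must be non-negative")
    z = (t - profile.t_peak) / profile.sigma
    return math.exp(-0.5 * z * z) / (profile.sigma * math.sqrt(2.0 * math.pi)) + x_t


@dataclass
class TransportGraph:
    """Delta-x node network carrying intravascular contrast agent."""

    pos: np.ndarray        # (N,2) mm
    radius: np.ndarray     # (N,) mm
    ntype: np.ndarray      # (N,) node type codes
    src: np.ndarray        # (E,) upstream node of each edge
    dst: np.ndarray        # (E,) downstream node
    area: np.ndarray       # (E,) face area pi r^2, mm^2
    dx: np.ndarray         # (E,) edge length, mm
    vel: np.ndarray        # (E,) face velocity along flow, mm/s
    diffusion: float       # intravascular D, mm^2/s
    root_nodes: np.ndarray
    root_area: np.ndarray
    root_vel: np.ndarray
    node_segment: np.ndarray = None
    term_cell: np.ndarray = None   # (T,2) mapped tissue cell indices
    C: np.ndarray = None
    volume: np.ndarray = field(default=None)  # (N,) control volumes, mm^3
    term_exchange_volume: np.ndarray = field(default=None)  # (T,) mm^3
    term_extraction: np.ndarray = field(default=None)  # (T,) in [0, 1]

    def __post_init__(self):
        if self.volume is None:
            # regular nodes own half of each adjacent interval (= pi r^2 dx);
            # roots, terminals and bifurcations own their full adjacent
            # intervals, so the explicit update keeps a non-negative
            # diagonal (discrete maximum principle) at the CFL limit even
            # where adjacent intervals have unequal spacing
            v = np.zeros(len(self.pos))
            full = self.area * self.dx
            np.add.at(v, self.src, full)
            np.add.at(v, self.dst, full)
            v[self.ntype == REGULAR] *= 0.5
            self.volume = v
        if self.C is None:
            self.C = np.zeros(len(self.pos))
        # terminal advective outflow: blood leaving each terminal node to
        # the (unmodeled) microcirculation carries contrast with it at
        # the face flux A*v of the terminal's single incoming edge
        term = self.terminal_nodes
        edge_of = np.full(self.n_nodes, -1, dtype=np.int64)
        edge_of[self.dst] = np.arange(len(self.dst))
        e = edge_of[term]
        self.term_outflow = np.where(e >= 0, self.area[e] * self.vel[e], 0.0)
        if self.term_exchange_volume is None:
            self.term_exchange_volume = self.volume[term].copy()
        if self.term_extraction is None:
            # fraction of each terminal's advective outflow delivered to
            # its tissue cell (first-pass extraction); the rest drains to
            # the unmodeled venous microcirculation.  Zero by default for
            # standalone kernels; the simulation driver sets it from the
            # endothelial permeability and the terminal's territory
            self.term_extraction = np.zeros(len(term))

    # ------------------------------------------------------------------ structure
    @property
    def n_nodes(self) -> int:
        return len(self.pos)

    @property
    def terminal_nodes(self) -> np.ndarray:
        if getattr(self, "_term_cache", None) is None:
            self._term_cache = np.nonzero(self.ntype == TERMINAL)[0]
        return self._term_cache

    def neighbors(self, i: int) -> list[int]:
        out = self.dst[self.src == i].tolist()
        out += self.src[self.dst == i].tolist()
        return sorted(out)

    def degree(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=int)
        np.add.at(d, self.src, 1)
        np.add.at(d, self.dst, 1)
        return d

    # ------------------------------------------------------------------ stepping
    def cfl_dt(self, permeability: float = 0.0) -> float:
        """Largest monotone explicit step.

        Per-node bound dt <= V_i / (sum of outgoing advective and all
        adjacent diffusive flux coefficients, plus P V_i at terminals).
        On a uniform interior line this reduces to the familiar bounds
        dx/v (pure advection) and dx^2/(2D) (pure diffusion); at
        junctions it generalizes them so the update diagonal never goes
        negative and the discrete maximum principle holds.
        """
        n = self.n_nodes
        coeff = np.bincount(self.src, weights=self.area * self.vel, minlength=n)
        if self.diffusion > 0:
            diff = self.area * self.diffusion / self.dx
            coeff += np.bincount(self.src, weights=diff, minlength=n)
            coeff += np.bincount(self.dst, weights=diff, minlength=n)
        term = self.terminal_nodes
        coeff[term] += self.term_outflow
        if permeability > 0:
            coeff[term] += permeability * self.term_exchange_volume
        active = coeff > 0
        if not active.any():
            raise CFLError("no finite CFL bound (no transport at all?)")
        return float(np.min(self.volume[active] / coeff[active]))

    def edge_fluxes(self, C: np.ndarray) -> np.ndarray:
        """Mass flux (mm^3 a.u./s) through every edge, positive downstream."""
        adv = self.vel * C[self.src]
        dif = -self.diffusion * (C[self.dst] - C[self.src]) / self.dx
        return self.area * (adv + dif)

    def step(
        self,
        dt: float,
        inflow: np.ndarray | float = 0.0,
        permeability: float = 0.0,
        tissue_C: np.ndarray | None = None,
        check_cfl: bool = True,
    ):
        """Advance all node concentrations one explicit-Euler step.

        Parameters
        ----------
        inflow : imposed root concentration Q(t)+X (scalar or one per root).
        permeability : endothelial P (1/s) for terminal leakage.
        tissue_C : extravascular concentration at each terminal's mapped
            cell (aligned with :attr:`terminal_nodes`); required when
            ``permeability > 0``.

        Returns
        -------
        dict with the step's mass budget: ``inflow_mass`` entering at the
        roots, ``leak_mass`` per terminal handed to the tissue, and
        ``outflow_mass`` leaving through the terminals into the
        microcirculation (advective washout).
        """
        if check_cfl and dt > self.cfl_dt(permeability) * (1 + 1e-12):
            raise CFLError(f"dt={dt} violates the CFL bound")
        C = self.C
        F = self.edge_fluxes(C)
        n = self.n_nodes
        rate = np.bincount(self.dst, weights=F, minlength=n)
        rate -= np.bincount(self.src, weights=F, minlength=n)
        in_rate = self.root_area * self.root_vel * inflow
        rate[self.root_nodes] += in_rate
        term = self.terminal_nodes
        out_rate = self.term_outflow * C[term]
        rate[term] -= out_rate
        # extracted fraction of the advective outflow perfuses the tissue;
        # the remainder drains to the venous microcirculation
        extracted_rate = self.term_extraction * out_rate
        venous_rate = out_rate - extracted_rate

        leak_mass = None
        if permeability > 0.0:
            if tissue_C is None:
                raise ValueError("terminal exchange requires tissue concentrations")
            diff = C[term] - np.asarray(tissue_C)
            # one-way endothelial valve: P * exchange volume * (C - Ce)+
            valve_rate = (
                permeability * self.term_exchange_volume * np.maximum(diff, 0.0)
            )
            rate[term] -= valve_rate
            leak_mass = (valve_rate + extracted_rate) * dt
        elif self.term_extraction.any():
            leak_mass = extracted_rate * dt
        self.C = C + dt * rate / self.volume
        return {
            "inflow_mass": float(in_rate.sum() * dt),
            "leak_mass": leak_mass,
            "outflow_mass": float(venous_rate.sum() * dt),
        }

    def total_mass(self, C: np.ndarray | None = None) -> float:
        C = self.C if C is None else C
        return float(np.dot(C, self.volume))


# ---------------------------------------------------------------------- single-node ops

def _node_update(graph: TransportGraph, i: int, C: np.ndarray, dt: float) -> float:
    """Flux-form update of one node (advection + diffusion only)."""
    rate = 0.0
    for e in np.nonzero(graph.dst == i)[0]:
        rate += graph.area[e] * (
            graph.vel[e] * C[graph.src[e]]
            - graph.diffusion * (C[i] - C[graph.src[e]]) / graph.dx[e]
        )
    for e in np.nonzero(graph.src == i)[0]:
        rate -= graph.area[e] * (
            graph.vel[e] * C[i]
            - graph.diffusion * (C[graph.dst[e]] - C[i]) / graph.dx[e]
        )
    return C[i] + dt * rate / graph.volume[i]


def step_regular(graph: TransportGraph, i: int, C: np.ndarray, dt: float) -> float:
    """One-node update of a regular (two-neighbour) node."""
    if graph.ntype[i] != REGULAR:
        raise ValueError(f"node {i} is not regular")
    if dt > graph.cfl_dt() * (1 + 1e-12):
        raise CFLError("dt violates the CFL bound")
    return _node_update(graph, i, C, dt)


def step_bifurcation(graph: TransportGraph, i: int, C: np.ndarray, dt: float) -> float:
    """One-node update of a bifurcation node (area-weighted faces)."""
    if graph.ntype[i] != BIFURCATION:
        raise ValueError(f"node {i} is not a bifurcation")
    if dt > graph.cfl_dt() * (1 + 1e-12):
        raise CFLError("dt violates the CFL bound")
    return _node_update(graph, i, C, dt)


def step_terminal(
    graph: TransportGraph,
    i: int,
    C: np.ndarray,
    tissue_c: float,
    dt: float,
    permeability: float,
) -> tuple[float, float]:
    """One-node update of a terminal node; returns (new C, leaked mass).

    The advective flux continues through the node into the unmodeled
    microcirculation (upwind in-minus-out form), and the leak P*(C - Ce)
    acts only when C > Ce (one-way endothelial valve).
    """
    if graph.ntype[i] != TERMINAL:
        raise ValueError(f"node {i} is not terminal")
    if dt > graph.cfl_dt(permeability) * (1 + 1e-12):
        raise CFLError("dt violates the CFL bound")
    t_idx = int(np.nonzero(graph.terminal_nodes == i)[0][0])
    c_new = _node_update(graph, i, C, dt)
    c_new -= dt * graph.term_outflow[t_idx] * C[i] / graph.volume[i]
    leak_mass_rate = (
        permeability
        * graph.term_exchange_volume[t_idx]
        * max(C[i] - tissue_c, 0.0)
    )
    return (
        c_new - dt * leak_mass_rate / graph.volume[i],
        leak_mass_rate * dt,
    )


# ---------------------------------------------------------------------- discretization

def discretize_tree(
    tree: ArterialTree,
    flow: FlowSolution,
    dx: float,
    diffusion: float = 1.0e-2,
) -> TransportGraph:
    """Split every segment into ceil(l/dx) intervals and build the node graph.

    Junction nodes (a segment's distal end with children) become
    bifurcation nodes carrying the parent radius; leaf distal ends become
    terminals; the tree inlet becomes the root node.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    lengths = tree.lengths()
    if lengths.min() < dx:
        warnings.warn(
            "dx exceeds the shortest segment length; such segments get a "
            "single interval",
            stacklevel=2,
        )
    pos, radius, ntype, nseg = [], [], [], []
    src, dst, area, edx, vel = [], [], [], [], []

    def new_node(p, r, t, s):
        pos.append(np.asarray(p, dtype=float))
        radius.append(r)
        ntype.append(t)
        nseg.append(s)
        return len(pos) - 1

    root_node = new_node(tree.prox[tree.root], tree.radius[tree.root], ROOT, tree.root)
    # preorder walk carrying the node id at each segment's proximal end
    stack = [(tree.root, root_node)]
    while stack:
        s, up = stack.pop()
        n_int = max(1, math.ceil(lengths[s] / dx))
        h = lengths[s] / n_int
        a = math.pi * tree.radius[s] ** 2
        v = flow.velocity[s]
        p0 = tree.prox[s]
        d0 = tree.dist[s]
        has_children = tree.left[s] >= 0
        prev = up
        for k in range(1, n_int + 1):
            point = p0 + (d0 - p0) * (k / n_int)
            if k < n_int:
                t = REGULAR
            else:
                t = BIFURCATION if has_children else TERMINAL
            node = new_node(point, tree.radius[s], t, s)
            src.append(prev)
            dst.append(node)
            area.append(a)
            edx.append(h)
            vel.append(v)
            prev = node
        if has_children:
            stack.append((tree.left[s], prev))
            stack.append((tree.right[s], prev))

    return TransportGraph(
        pos=np.asarray(pos),
        radius=np.asarray(radius),
        ntype=np.asarray(ntype, dtype=np.int8),
        src=np.asarray(src, dtype=np.int64),
        dst=np.asarray(dst, dtype=np.int64),
        area=np.asarray(area),
        dx=np.asarray(edx),
        vel=np.asarray(vel),
        diffusion=diffusion,
        root_nodes=np.asarray([root_node], dtype=np.int64),
        root_area=np.asarray([math.pi * tree.radius[tree.root] ** 2]),
        root_vel=np.asarray([flow.velocity[tree.root]]),
        node_segment=np.asarray(nseg, dtype=np.int64),
    )


def merge_graphs(graphs: list[TransportGraph]) -> TransportGraph:
    """Concatenate per-tree graphs into one multi-root system graph."""
    if not graphs:
        raise ValueError("no graphs to merge")
    off = np.cumsum([0] + [g.n_nodes for g in graphs[:-1]])
    return TransportGraph(
        pos=np.concatenate([g.pos for g in graphs]),
        radius=np.concatenate([g.radius for g in graphs]),
        ntype=np.concatenate([g.ntype for g in graphs]),
        src=np.concatenate([g.src + o for g, o in zip(graphs, off)]),
        dst=np.concatenate([g.dst + o for g, o in zip(graphs, off)]),
        area=np.concatenate([g.area for g in graphs]),
        dx=np.concatenate([g.dx for g in graphs]),
        vel=np.concatenate([g.vel for g in graphs]),
        diffusion=graphs[0].diffusion,
        root_nodes=np.concatenate([g.root_nodes + o for g, o in zip(graphs, off)]),
        root_area=np.concatenate([g.root_area for g in graphs]),
        root_vel=np.concatenate([g.root_vel for g in graphs]),
        node_segment=np.concatenate([g.node_segment for g in graphs]),
    )


def map_terminals_to_cells(graph: TransportGraph, domain) -> None:
    """Assign every terminal node its nearest masked tissue cell, one-to-one.

    Nearest by Euclidean distance to the cell center; ties break toward the
    lowest cell index; when a cell is already taken the next-nearest free
    cell is used.  Stored on ``graph.term_cell`` as (ix, iy) pairs aligned
    with ``graph.terminal_nodes``.

    """
    term = graph.terminal_nodes
    ixs, iys = np.nonzero(domain.mask)
    centers = np.column_stack([(ixs + 0.5), (iys + 0.5)]) * domain.cell_size
    tree = cKDTree(centers)
    taken = np.zeros(len(centers), dtype=bool)
    cells = np.empty((len(term), 2), dtype=np.int64)
    k0 = min(8, len(centers))
    for t_i, node in enumerate(term):
        k = k0
        while True:
            dd, ii = tree.query(graph.pos[node], k=k)
            ii = np.atleast_1d(ii)
            free = ii[~taken[ii]]
            if len(free):
                c = int(free[0])
                taken[c] = True
                cells[t_i] = (ixs[c], iys[c])
                break
            if k >= len(centers):
                raise RuntimeError("more terminals than masked cells")
            k = min(2 * k, len(centers))
    graph.term_cell = cells
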