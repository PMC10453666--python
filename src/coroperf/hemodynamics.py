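"""Steady Poiseuille hemodynamics on an arterial tree.

Flows are set by the terminal outflows and aggregated up the tree
(exact mass conservation at every bifurcation); pressures follow from
the per-segment Poiseuille drop dp_s = R_s * Q_s accumulated from the
root perfusion pressure; the mean cross-sectional velocity of segment j
is v_j = Q_j / (pi r_j^2).

A stenosis is modelled as a flow reduction: the terminal outflows of the
obstructed subtree are divided by the severity factor alpha while the
tree's root inflow is held at Q_perf by redistributing the removed flow
proportionally over the unobstructed terminals (switchable off, in which
case the root inflow simply drops).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cco import MMHG_TO_PA, ArterialTree, segment_resistance


@dataclass(frozen=True)
class StenosisSpec:
    """Flow obstruction at the root segment of a subtree.

    site : segment id whose subtree is obstructed.
    alpha : severity; subtree terminal outflows are divided by alpha
        (alpha = 1 means healthy, 25 ischemia, 30 infarction).
    """

    site: int
    alpha: float

    def __post_init__(self):
        if self.alpha < 1.0:
            raise ValueError("stenosis factor alpha must be >= 1")


@dataclass
class FlowSolution:
    """Per-segment steady-flow state of one tree."""

    flow: np.ndarray          # mm^3/s
    pressure_distal: np.ndarray  # mmHg at each segment's distal node
    velocity: np.ndarray      # mm/s
    terminal_flow: np.ndarray  # mm^3/s per segment (0 for non-terminals)

    def terminal_flow_sum(self) -> float:
        return float(self.terminal_flow.sum())


def segment_velocity(q: float, r: float) -> float:
    """Mean velocity Q/(pi r^2) of Poiseuille flow in a cylinder (mm/s)."""
    if r <= 0:
        raise ValueError("radius must be positive")
    return q / (math.pi * r * r)


def solve_flow(
    tree: ArterialTree,
    stenosis: StenosisSpec | None = None,
    redistribute: bool = True,
) -> FlowSolution:
    """Solve segment flows, distal pressures and velocities.

    Baseline terminal outflows are Q_perf/N_term each.  With a stenosis,
    obstructed-subtree terminals are divided by alpha and (by default)
    the removed flow is spread proportionally over the remaining
    terminals so the root inflow stays exactly Q_perf.
    """
    n = tree.n_segments
    if n == 0:
        raise ValueError("empty tree")
    params = tree.params
    left = np.asarray(tree.left)
    is_term = left < 0

    qt = np.zeros(n)
    qt[is_term] = params.q_perf / tree.n_terminals

    if stenosis is not None and stenosis.alpha != 1.0:
        if not (0 <= stenosis.site < n):
            raise ValueError(f"stenosis site {stenosis.site} not in tree")
        sub = np.asarray(tree.subtree_ids(stenosis.site))
        in_sub = np.zeros(n, dtype=bool)
        in_sub[sub] = True
        obstructed = is_term & in_sub
        if obstructed.all():
            raise ValueError("cannot obstruct the whole tree and keep root flow")
        q_sub = qt[obstructed].sum()
        qt[obstructed] /= stenosis.alpha
        if redistribute:
            others = is_term & ~in_sub
            scale = (params.q_perf - q_sub / stenosis.alpha) / (
                params.q_perf - q_sub
            )
            qt[others] *= scale

    # aggregate terminal outflows up the tree (children before parents)
    from .cco import _post_order

    order = _post_order(
        tree.root, np.asarray(tree.left, dtype=np.int64),
        np.asarray(tree.right, dtype=np.int64), n,
    )
    flow = qt.copy()
    for s in order:
        l = tree.left[s]
        if l >= 0:
            flow[s] = flow[l] + flow[tree.right[s]]

    lengths = tree.lengths()
    radius = np.asarray(tree.radius)
    resistance = 8.0 * params.eta * lengths / (np.pi * radius**4)

    # accumulate pressures root -> distal ends (preorder)
    p = np.zeros(n)
    p_root_pa = params.p_perf_mmhg * MMHG_TO_PA
    for s in order[::-1]:
        par = tree.parent[s]
        upstream = p_root_pa if par < 0 else p[par]
        p[s] = upstream - resistance[s] * flow[s]
    velocity = flow / (np.pi * radius**2)
    return FlowSolution(
        flow=flow,
        pressure_distal=p / MMHG_TO_PA,
        velocity=velocity,
        terminal_flow=qt,
    )


def subtree_inflow(tree: ArterialTree, sol: FlowSolution, site: int) -> float:
    """Inflow (mm^3/s) of the subtree rooted at ``site``."""
    return float(sol.flow[site])


def find_segment_near(
    tree: ArterialTree, point, min_subtree_terminals: int = 1,
    max_terminal_fraction: float = 1.0,
) -> int:
    """Segment whose midpoint is nearest to a physical point.

    Useful for picking a stenosis site graphically ("a branch close to
    the right side of the endocardium"): restrict to branches feeding at
    least ``min_subtree_terminals`` and at most a fraction of the tree's
    terminals so the obstruction has a territory without taking out the
    whole tree.
    """
    point = np.asarray(point, dtype=float)
    mids = 0.5 * (np.asarray(tree.prox) + np.asarray(tree.dist))
    nterm = np.asarray(tree.nterm)
    ok = (nterm >= min_subtree_terminals) & (
        nterm <= max_terminal_fraction * tree.n_terminals
    )
    if not ok.any():
        raise ValueError("no segment satisfies the subtree-size bounds")
    d = np.linalg.norm(mids - point, axis=1)
    d[~ok] = np.inf
    return int(np.argmin(d))


def flow_table(tree: ArterialTree, sol: FlowSolution):
    """CSV-ready per-segment table (id, Q, p, v, r, l)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "segment": np.arange(tree.n_segments),
            "flow_mm3_s": sol.flow,
            "pressure_distal_mmhg": sol.pressure_distal,
            "velocity_mm_s": sol.velocity,
            "radius_mm": np.asarray(tree.radius),
            "length_mm": tree.lengths(),
        }
    )
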