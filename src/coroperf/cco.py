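"""Constrained constructive optimization (CCO) of coronary arterial trees.

A binary tree of rigid straight cylindrical segments is grown inside a
perfusion territory by adding one terminal at a time.  Each new terminal
site is sampled at random (rejected when too close to the existing tree),
trial connections to the nearest segments are formed, and the bifurcation
point of each trial is optimized to minimize the total intravascular
volume

    V = pi * sum_s l_s * r_s**2 .

Hemodynamic constraints hold throughout growth: Poiseuille resistance
R_s = 8 eta l_s / (pi r_s**4) per segment, equal terminal outflows
Q_term = Q_perf / N_term, a common terminal pressure p_term against the
root perfusion pressure p_perf, and a power-law radius relation at every
bifurcation, r_parent**gamma = r_left**gamma + r_right**gamma (gamma = 3,
Murray's law, by default).  Radii are obtained exactly (to roundoff) by a
bottom-up reduced-resistance sweep followed by a top-down rescale.

Internal units are mm / s / Pa; flows in mm^3/s.  Configuration values in
clinical units (mL/min, mmHg) are converted at the boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

try:  # hot loop; pure-Python fallback keeps the package importable without JIT
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not a else a[0]

MMHG_TO_PA = 133.322
MLMIN_TO_MM3S = 1000.0 / 60.0

_PENALTY = 1.0e12


class GrowthError(RuntimeError):
    """Raised when tree growth cannot place a terminal."""


@dataclass(frozen=True)
class CCOParams:
    """Generation parameters for one arterial tree.

    q_perf_ml_min : perfusion inflow of the tree, mL/min.
    p_perf_mmhg, p_term_mmhg : root and terminal pressures, mmHg.
    n_term : number of terminal segments to grow.
    gamma : bifurcation-law exponent (2.55..3; 3 = Murray's law).
    eta : blood viscosity, Pa s.
    seed : RNG seed for terminal-site sampling.
    d_thresh_scale : scale of the minimum-distance rejection threshold,
        d_thresh = scale * sqrt(A_region / k_term); shrunk by 0.9 after
        every 10 consecutive rejections.
    n_candidate_segments : number of nearest segments tried per terminal.
    opt_tol : simplex tolerance (mm) for the bifurcation-point search.
    """

    q_perf_ml_min: float = 1.0
    p_perf_mmhg: float = 100.0
    p_term_mmhg: float = 60.0
    n_term: int = 119
    gamma: float = 3.0
    eta: float = 3.6e-3
    seed: int = 0
    d_thresh_scale: float = 1.0
    n_candidate_segments: int = 20
    opt_tol: float = 1.0e-6
    opt_maxfev: int = 120
    # segments below the transport resolution (dx = 0.25 mm) are not
    # representable on the node graph and would throttle the explicit step
    min_segment_length: float = 0.25
    max_sample_attempts: int = 2000

    def __post_init__(self):
        if self.q_perf_ml_min <= 0:
            raise ValueError("Q_perf must be positive")
        if self.p_perf_mmhg <= self.p_term_mmhg:
            raise ValueError("p_perf must exceed p_term")
        if not (2.55 <= self.gamma <= 3.0):
            raise ValueError("gamma must lie in [2.55, 3]")
        if self.n_term < 1:
            raise ValueError("n_term must be >= 1")

    @property
    def q_perf(self) -> float:
        """Perfusion flow in mm^3/s."""
        return self.q_perf_ml_min * MLMIN_TO_MM3S

    @property
    def dp(self) -> float:
        """Overall pressure drop p_perf - p_term in Pa."""
        return (self.p_perf_mmhg - self.p_term_mmhg) * MMHG_TO_PA


@dataclass
class Segment:
    """Read-only view of one vessel segment."""

    id: int
    proximal_point: np.ndarray
    distal_point: np.ndarray
    radius: float
    length: float
    flow: float
    resistance: float
    parent: int
    left: int
    right: int


def segment_resistance(length: float, radius: float, eta: float) -> float:
    """Poiseuille resistance 8*eta*l/(pi*r^4) of a cylindrical segment (Pa s/mm^3)."""
    if length <= 0 or radius <= 0:
        raise ValueError("segment length and radius must be positive")
    return 8.0 * eta * length / (math.pi * radius**4)


@njit(cache=False)
def _radii_core(post_order, left, right, length, nterm, gamma, qterm, dp, eta):
    """Bottom-up reduced resistances + top-down radii.

    Returns (radius, volume).  ``nterm`` is the per-subtree terminal count;
    subtree flow is nterm*qterm.  Reduced resistance Rstar_s is the subtree
    resistance seen at s's inlet multiplied by r_s^4, which depends only on
    lengths and the daughter/parent radius ratios (beta), not on the
    absolute radii; the root radius then follows from the global pressure
    drop and the radii propagate down via the betas.
    """
    n = length.shape[0]
    c = 8.0 * eta / math.pi
    rstar = np.empty(n)
    bl = np.ones(n)
    br = np.ones(n)
    for k in range(n):
        s = post_order[k]
        l = left[s]
        if l < 0:
            rstar[s] = c * length[s]
        else:
            r = right[s]
            # r_l/r_r from equal pressure drop across the two subtrees
            x = (nterm[l] * rstar[l] / (nterm[r] * rstar[r])) ** 0.25
            b_l = (1.0 + x ** (-gamma)) ** (-1.0 / gamma)
            b_r = (1.0 + x ** gamma) ** (-1.0 / gamma)
            bl[s] = b_l
            br[s] = b_r
            rstar[s] = c * length[s] + 1.0 / (
                b_l**4 / rstar[l] + b_r**4 / rstar[r]
            )
    root = post_order[n - 1]
    r_root = (nterm[root] * qterm * rstar[root] / dp) ** 0.25
    radius = np.zeros(n)
    stack_id = np.empty(n, dtype=np.int64)
    stack_r = np.empty(n)
    top = 0
    stack_id[0] = root
    stack_r[0] = r_root
    top = 1
    volume = 0.0
    while top > 0:
        top -= 1
        s = stack_id[top]
        rs = stack_r[top]
        radius[s] = rs
        volume += length[s] * rs * rs
        if left[s] >= 0:
            stack_id[top] = left[s]
            stack_r[top] = bl[s] * rs
            top += 1
            stack_id[top] = right[s]
            stack_r[top] = br[s] * rs
            top += 1
    return radius, math.pi * volume


def _post_order(root: int, left, right, n: int) -> np.ndarray:
    """Iterative post-order traversal (children before parents)."""
    order = np.empty(n, dtype=np.int64)
    stack = [root]
    k = n
    while stack:
        s = stack.pop()
        k -= 1
        order[k] = s  # reverse of root-first = post-order for binary trees
        if left[s] >= 0:
            stack.append(left[s])
            stack.append(right[s])
    return order


class ArterialTree:
    """Binary tree of cylindrical vessel segments grown by CCO."""

    def __init__(self, params: CCOParams, region: str = ""):
        self.params = params
        self.region = region
        self.prox: list[np.ndarray] = []
        self.dist: list[np.ndarray] = []
        self.parent: list[int] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.nterm: list[int] = []  # terminals in subtree rooted at s
        self.radius = np.zeros(0)
        self.root = 0

    # ------------------------------------------------------------------ basics
    @property
    def n_segments(self) -> int:
        return len(self.prox)

    @property
    def n_terminals(self) -> int:
        return self.nterm[self.root] if self.n_segments else 0

    def terminal_ids(self) -> np.ndarray:
        left = np.asarray(self.left)
        return np.nonzero(left < 0)[0]

    def bifurcation_ids(self) -> np.ndarray:
        left = np.asarray(self.left)
        return np.nonzero(left >= 0)[0]

    def lengths(self) -> np.ndarray:
        p = np.asarray(self.prox)
        d = np.asarray(self.dist)
        return np.linalg.norm(d - p, axis=1)

    @property
    def q_term(self) -> float:
        """Per-terminal outflow at the current growth stage (mm^3/s)."""
        return self.params.q_perf / self.n_terminals

    def flows(self) -> np.ndarray:
        """Baseline segment flows: subtree terminal count times Q_term (mm^3/s)."""
        return np.asarray(self.nterm, dtype=float) * self.q_term

    def segment(self, s: int) -> Segment:
        length = float(np.linalg.norm(self.dist[s] - self.prox[s]))
        flow = self.nterm[s] * self.q_term
        return Segment(
            id=s,
            proximal_point=self.prox[s].copy(),
            distal_point=self.dist[s].copy(),
            radius=float(self.radius[s]),
            length=length,
            flow=flow,
            resistance=segment_resistance(length, float(self.radius[s]), self.params.eta),
            parent=self.parent[s],
            left=self.left[s],
            right=self.right[s],
        )

    def path_to_root(self, s: int) -> list[int]:
        path = []
        while s >= 0:
            path.append(s)
            s = self.parent[s]
        return path

    def subtree_ids(self, s: int) -> list[int]:
        out, stack = [], [s]
        while stack:
            j = stack.pop()
            out.append(j)
            if self.left[j] >= 0:
                stack.extend((self.left[j], self.right[j]))
        return out

    # ------------------------------------------------------------------ radii
    def rescale_radii(self) -> None:
        """Recompute all radii so terminal pressures equal p_term exactly.

        Idempotent: radii depend only on topology, geometry and flows.
        """
        if self.n_segments == 0:
            raise GrowthError("empty tree")
        left = np.asarray(self.left, dtype=np.int64)
        right = np.asarray(self.right, dtype=np.int64)
        order = _post_order(self.root, left, right, self.n_segments)
        radius, _ = _radii_core(
            order,
            left,
            right,
            self.lengths(),
            np.asarray(self.nterm, dtype=float),
            self.params.gamma,
            self.q_term,
            self.params.dp,
            self.params.eta,
        )
        self.radius = radius

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "params": {
                k: getattr(self.params, k)
                for k in CCOParams.__dataclass_fields__
            },
            "root": self.root,
            "segments": [
                {
                    "id": s,
                    "prox": [float(v) for v in self.prox[s]],
                    "dist": [float(v) for v in self.dist[s]],
                    "radius": float(self.radius[s]),
                    "parent": self.parent[s],
                    "left": self.left[s],
                    "right": self.right[s],
                    "nterm": self.nterm[s],
                }
                for s in range(self.n_segments)
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "ArterialTree":
        params = CCOParams(**d["params"])
        tree = cls(params, region=d.get("region", ""))
        segs = sorted(d["segments"], key=lambda s: s["id"])
        for s in segs:
            tree.prox.append(np.asarray(s["prox"], dtype=float))
            tree.dist.append(np.asarray(s["dist"], dtype=float))
            tree.parent.append(s["parent"])
            tree.left.append(s["left"])
            tree.right.append(s["right"])
            tree.nterm.append(s["nterm"])
        tree.radius = np.asarray([s["radius"] for s in segs], dtype=float)
        tree.root = d.get("root", 0)
        return tree

    @classmethod
    def load_json(cls, path) -> "ArterialTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def tree_volume(tree: ArterialTree) -> float:
    """Total intravascular volume pi * sum(l_s r_s^2), mm^3."""
    if tree.n_segments == 0:
        raise GrowthError("empty tree")
    return float(np.pi * np.sum(tree.lengths() * np.asarray(tree.radius) ** 2))


def bifurcation_exponent(
    r0: float, r1: float, r2: float, lo: float = 2.0, hi: float = 4.0,
    tol: float = 1.0e-12,
) -> float:
    """Recover x solving r0^x = r1^x + r2^x by bisection on [lo, hi].

    f(x) = (r1/r0)^x + (r2/r0)^x - 1 is strictly decreasing for daughter
    radii below the parent radius, so the root is unique when bracketed.
    """
    a, b = math.log(r1 / r0), math.log(r2 / r0)

    def f(x):
        return math.exp(a * x) + math.exp(b * x) - 1.0

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError("exponent not bracketed in [lo, hi]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if flo * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------- geometry helpers

def _point_segment_distances(p: np.ndarray, prox: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Distance from point p to each segment (vectorized)."""
    d = dist - prox
    ll = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,ij->i", p - prox, d) / np.maximum(ll, 1e-30), 0.0, 1.0)
    proj = prox + t[:, None] * d
    return np.linalg.norm(p - proj, axis=1)


def _segments_intersect(a0, a1, b0, b1, eps=1e-12) -> bool:
    """Proper intersection test for two 2D segments (shared endpoints ignored)."""
    def cross(o, p, q):
        return (p[0] - o[0]) * (q[1] - o[1]) - (p[1] - o[1]) * (q[0] - o[0])

    for e0, e1 in ((a0, b0), (a0, b1), (a1, b0), (a1, b1)):
        if np.linalg.norm(e0 - e1) < eps:
            return False
    d1 = cross(b0, b1, a0)
    d2 = cross(b0, b1, a1)
    d3 = cross(a0, a1, b0)
    d4 = cross(a0, a1, b1)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


# ---------------------------------------------------------------------- trial connections

class _Trial:
    """Trial topology for connecting a new terminal to segment j.

    Segment j (A->B) is split at a bifurcation point X into A->X (keeps
    j's id), X->B (new id k, inherits j's children) and X->p (new terminal
    id t).  The bifurcation point is optimized in the barycentric interior
    of triangle (A, B, p).
    """

    def __init__(self, tree: ArterialTree, j: int, p: np.ndarray):
        self.tree = tree
        self.j = j
        self.p = np.asarray(p, dtype=float)
        n = tree.n_segments
        self.k = n
        self.t = n + 1
        self.left = np.asarray(tree.left + [tree.left[j], -1], dtype=np.int64)
        self.right = np.asarray(tree.right + [tree.right[j], -1], dtype=np.int64)
        self.left[j] = self.k
        self.right[j] = self.t
        nterm = np.asarray(tree.nterm + [tree.nterm[j], 1], dtype=float)
        for s in tree.path_to_root(j):
            nterm[s] += 1.0
        self.nterm = nterm
        self.lengths = np.concatenate([tree.lengths(), [0.0, 0.0]])
        self.A = tree.prox[j]
        self.B = tree.dist[j]
        self.order = _post_order(tree.root, self.left, self.right, n + 2)
        self.qterm = tree.params.q_perf / nterm[tree.root]

    def bif_point(self, uv) -> np.ndarray:
        u, v = uv
        return u * self.A + v * self.B + (1.0 - u - v) * self.p

    def volume_at(self, uv) -> float:
        u, v = uv
        m = 1e-6
        if u < m or v < m or u + v > 1.0 - m:
            return _PENALTY
        x = self.bif_point(uv)
        pr = self.tree.params
        la = np.linalg.norm(x - self.A)
        lb = np.linalg.norm(self.B - x)
        lp = np.linalg.norm(self.p - x)
        if min(la, lb, lp) < pr.min_segment_length:
            return _PENALTY
        self.lengths[self.j] = la
        self.lengths[self.k] = lb
        self.lengths[self.t] = lp
        _, vol = _radii_core(
            self.order, self.left, self.right, self.lengths, self.nterm,
            pr.gamma, self.qterm, pr.dp, pr.eta,
        )
        return vol

    def optimize(self) -> tuple[float, np.ndarray]:
        """Minimize tree volume over the bifurcation point; return (volume, X)."""
        pr = self.tree.params
        res = minimize(
            self.volume_at,
            x0=np.array([1.0 / 3.0, 1.0 / 3.0]),
            method="Nelder-Mead",
            options={
                "xatol": pr.opt_tol,
                "fatol": pr.opt_tol,
                "maxfev": pr.opt_maxfev,
            },
        )
        return float(res.fun), self.bif_point(res.x)


def optimize_connection(tree: ArterialTree, j: int, p: np.ndarray):
    """Optimized trial connection of point p to segment j.

    Returns ``(volume, bifurcation_point)``; volume is the total tree
    volume the connection would produce (large penalty value if no valid
    interior point exists).
    """
    return _Trial(tree, j, np.asarray(p, dtype=float)).optimize()


def _connection_valid(tree, domain, region, j, x, p, params) -> bool:
    """Geometric validity of a committed connection candidate."""
    pts = [x]
    for e0, e1 in ((tree.prox[j], x), (x, tree.dist[j]), (x, p)):
        pts.append(0.5 * (np.asarray(e0) + np.asarray(e1)))
        if np.linalg.norm(np.asarray(e1) - np.asarray(e0)) < params.min_segment_length:
            return False
    pts = np.asarray(pts)
    if not domain.points_inside(pts).all():
        return False
    if not domain.points_inside(np.asarray([x]), region=region).all():
        return False
    # new terminal segment must not cross existing segments
    prox = np.asarray(tree.prox)
    dist = np.asarray(tree.dist)
    mids = 0.5 * (prox + dist)
    near = np.argsort(np.linalg.norm(mids - p, axis=1))[:30]
    for s in near:
        if s == j:
            continue
        if _segments_intersect(x, p, prox[s], dist[s]):
            return False
    return True


def _commit_connection(tree: ArterialTree, j: int, x: np.ndarray, p: np.ndarray):
    k = tree.n_segments
    t = k + 1
    B = tree.dist[j]
    # X -> B keeps j's children
    tree.prox.append(x.copy())
    tree.dist.append(np.asarray(B, dtype=float).copy())
    tree.parent.append(j)
    tree.left.append(tree.left[j])
    tree.right.append(tree.right[j])
    tree.nterm.append(tree.nterm[j])
    for c in (tree.left[j], tree.right[j]):
        if c >= 0:
            tree.parent[c] = k
    # X -> p new terminal
    tree.prox.append(x.copy())
    tree.dist.append(np.asarray(p, dtype=float).copy())
    tree.parent.append(j)
    tree.left.append(-1)
    tree.right.append(-1)
    tree.nterm.append(1)
    # j becomes A -> X
    tree.dist[j] = x.copy()
    tree.left[j] = k
    tree.right[j] = t
    for s in tree.path_to_root(j):
        tree.nterm[s] += 1


# ---------------------------------------------------------------------- growth

def root_inlet_point(domain, region) -> np.ndarray:
    """Root inlet on the epicardial rim at the sector's mid-angle."""
    from .domain import REGION_NAMES, _wrap_angle

    idx = REGION_NAMES.index(region) if isinstance(region, str) else region
    a0, a1 = domain.angular_splits[idx]
    a0 = float(_wrap_angle(a0))
    a1 = float(_wrap_angle(a1))
    if a1 <= a0:
        a1 += 2.0 * np.pi
    mid = 0.5 * (a0 + a1)
    r = domain.outer_radius - 0.75 * domain.cell_size
    return np.array(
        [domain.center[0] + r * np.cos(mid), domain.center[1] + r * np.sin(mid)]
    )


def _sample_point(rng, cells_xy, cell_size) -> np.ndarray:
    i = rng.integers(len(cells_xy))
    return cells_xy[i] + (rng.random(2) - 0.5) * cell_size


def grow_tree(domain, region, params: CCOParams, rng=None) -> ArterialTree:
    """Grow one CCO tree with ``params.n_term`` terminals inside a territory.

    Terminal sites are sampled uniformly over the territory's cells and
    rejected when closer than a distance threshold to the existing tree;
    the threshold shrinks by 0.9 after every 10 consecutive rejections.
    Each accepted site is connected at the volume-optimal bifurcation
    point among the ``n_candidate_segments`` nearest segments.
    """
    region_name = region if isinstance(region, str) else str(region)
    rmask = domain.region_mask(region)
    if not rmask.any():
        raise GrowthError(f"perfusion region {region!r} is empty")
    x, y = domain.cell_centers()
    cells_xy = np.column_stack([x[rmask], y[rmask]])
    area = rmask.sum() * domain.cell_area
    rng = np.random.default_rng(params.seed) if rng is None else rng

    tree = ArterialTree(params, region=region_name)
    inlet = root_inlet_point(domain, region)

    # first terminal: require a reasonable root length
    d0 = params.d_thresh_scale * math.sqrt(area / max(params.n_term, 1))
    for _ in range(params.max_sample_attempts):
        p = _sample_point(rng, cells_xy, domain.cell_size)
        if np.linalg.norm(p - inlet) > max(d0, 3 * domain.cell_size):
            break
    else:  # pragma: no cover
        raise GrowthError("could not place the first terminal")
    tree.prox.append(inlet.copy())
    tree.dist.append(p.copy())
    tree.parent.append(-1)
    tree.left.append(-1)
    tree.right.append(-1)
    tree.nterm.append(1)
    tree.rescale_radii()

    attempts = 0
    while tree.n_terminals < params.n_term:
        k = tree.n_terminals
        d_thresh = params.d_thresh_scale * math.sqrt(area / (k + 1))
        fails = 0
        placed = False
        while not placed:
            attempts += 1
            if attempts > params.max_sample_attempts * params.n_term:
                raise GrowthError(
                    f"terminal placement failed after {attempts} attempts"
                )
            p = _sample_point(rng, cells_xy, domain.cell_size)
            prox = np.asarray(tree.prox)
            dist = np.asarray(tree.dist)
            dists = _point_segment_distances(p, prox, dist)
            if dists.min() < d_thresh:
                fails += 1
                if fails % 10 == 0:
                    d_thresh *= 0.9
                continue
            # trial connections to the nearest segments
            cand = np.argsort(dists)[: params.n_candidate_segments]
            best = None
            for j in cand:
                vol, xb = optimize_connection(tree, int(j), p)
                if vol >= _PENALTY:
                    continue
                if not _connection_valid(tree, domain, region, int(j), xb, p, params):
                    continue
                if best is None or vol < best[0]:
                    best = (vol, int(j), xb)
            if best is None:
                fails += 1
                if fails % 10 == 0:
                    d_thresh *= 0.9
                continue
            _commit_connection(tree, best[1], best[2], p)
            tree.rescale_radii()
            placed = True
    return tree


def split_terminals(n_total: int, n_trees: int = 3) -> list[int]:
    """Split a system-wide terminal count as evenly as possible across trees."""
    base = n_total // n_trees
    extra = n_total % n_trees
    return [base + (1 if i < extra else 0) for i in range(n_trees)]


def grow_system(domain, params: CCOParams, n_term_total: int = 355):
    """Grow the three coronary trees (LCX/LAD/RCA) over their territories.

    The system terminal count is split as evenly as possible; every tree
    gets the same perfusion flow and pressures.  Per-tree seeds are
    derived from ``params.seed`` so trees are independent but the whole
    system is reproducible.
    """
    from .domain import REGION_NAMES

    trees = []
    for i, (name, nt) in enumerate(zip(REGION_NAMES, split_terminals(n_term_total))):
        p = replace(params, n_term=nt, seed=(params.seed * 7919 + i) % (2**31))
        trees.append(grow_tree(domain, name, p))
    return trees


# ---------------------------------------------------------------------- morphometry

def morphometry(tree: ArterialTree) -> pd.DataFrame:
    """Per-segment morphometric table: flow (mL/min), length and radius (mm)."""
    flows = tree.flows() / MLMIN_TO_MM3S
    return pd.DataFrame(
        {
            "segment": np.arange(tree.n_segments),
            "flow_ml_min": flows,
            "length_mm": tree.lengths(),
            "radius_mm": np.asarray(tree.radius),
            "is_terminal": np.asarray(tree.left) < 0,
            "nterm": np.asarray(tree.nterm),
        }
    )


def morphometry_histograms(tree: ArterialTree, bins: int = 20) -> dict:
    """Histograms of segment flow, length and radius (counts sum to k_tot)."""
    tab = morphometry(tree)
    out = {}
    for col in ("flow_ml_min", "length_mm", "radius_mm"):
        counts, edges = np.histogram(tab[col].to_numpy(), bins=bins)
        out[col] = {"counts": counts, "edges": edges}
    return out
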