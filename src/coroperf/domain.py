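"""2D myocardial slice geometry.

The tissue domain is a short-axis slice of the left ventricular wall,
modelled as an annulus between the endocardial (inner) and epicardial
(outer) contours, embedded in a square cell-centered finite-volume grid.
The annulus is partitioned into three equal-area angular sectors, one per
main coronary artery (LCX, LAD, RCA), each perfused by its own arterial
tree.  A subendocardial patch can be marked as fibrotic scar for the
infarction scenario, and matching remote/damaged evaluation regions of
interest are defined for signal read-out.

Conventions: 0-based cell indexing ``(ix, iy)``, physical coordinates at
cell centers, origin at the grid's lower-left corner, lengths in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

REGION_NAMES = ("LCX", "LAD", "RCA")
REGION_NONE = -1

EPICARDIUM = "epicardium"
ENDOCARDIUM = "endocardium"

# face offsets: (+x, -x, +y, -y)
_FACE_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1))

TWO_PI = 2.0 * np.pi


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent domain geometry."""


def _wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Map angles to [0, 2*pi)."""
    return np.mod(theta, TWO_PI)


def _in_sector(theta, start, end):
    """Membership of wrapped angles in the sector [start, end), with wrap-around."""
    theta = _wrap_angle(theta)
    start = float(_wrap_angle(start))
    end = float(_wrap_angle(end))
    if np.isclose(start, end):  # full circle
        return np.ones_like(np.asarray(theta), dtype=bool)
    if start < end:
        return (theta >= start) & (theta < end)
    return (theta >= start) | (theta < end)


@dataclass
class MyocardialDomain:
    """Masked annular slice on a uniform square grid.

    Attributes
    ----------
    grid_shape : (int, int)
        Cells per axis.
    cell_size : float
        Cell edge length in mm.
    mask : ndarray of bool, shape grid_shape
        True inside the myocardium.
    perfusion_region : ndarray of int, shape grid_shape
        Index into :data:`REGION_NAMES`, or ``REGION_NONE`` outside.
    fibrosis_mask, roi_remote, roi_damaged : ndarray of bool
        Fibrotic scar and evaluation regions (subsets of ``mask``).
    inner_radius, outer_radius : float
        Endocardial / epicardial radii in mm.
    center : (float, float)
        Annulus center in physical coordinates.
    """

    grid_shape: tuple[int, int]
    cell_size: float
    mask: np.ndarray
    perfusion_region: np.ndarray
    inner_radius: float
    outer_radius: float
    center: tuple[float, float]
    angular_splits: tuple = ()
    fibrosis_mask: np.ndarray = field(default=None)
    roi_remote: np.ndarray = field(default=None)
    roi_damaged: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.fibrosis_mask is None:
            self.fibrosis_mask = np.zeros(self.grid_shape, dtype=bool)
        if self.roi_remote is None:
            self.roi_remote = np.zeros(self.grid_shape, dtype=bool)
        if self.roi_damaged is None:
            self.roi_damaged = np.zeros(self.grid_shape, dtype=bool)

    # ------------------------------------------------------------------ geometry
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical x/y coordinates of cell centers (2D arrays)."""
        nx, ny = self.grid_shape
        x = (np.arange(nx) + 0.5) * self.cell_size
        y = (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(x, y, indexing="ij")

    def polar(self) -> tuple[np.ndarray, np.ndarray]:
        """Radius and wrapped angle of every cell center relative to the annulus center."""
        x, y = self.cell_centers()
        dx = x - self.center[0]
        dy = y - self.center[1]
        return np.hypot(dx, dy), _wrap_angle(np.arctan2(dy, dx))

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def cell_volume(self) -> float:
        """Cell volume in mm^3 assuming unit (1 mm) slice thickness."""
        return self.cell_area * 1.0

    def masked_area(self) -> float:
        return float(self.mask.sum()) * self.cell_area

    def region_mask(self, region) -> np.ndarray:
        """Boolean mask of one perfusion territory (by name or index)."""
        if isinstance(region, str):
            region = REGION_NAMES.index(region)
        return self.perfusion_region == region

    def region_counts(self) -> dict[str, int]:
        return {
            name: int((self.perfusion_region == i).sum())
            for i, name in enumerate(REGION_NAMES)
        }

    # ------------------------------------------------------------------ boundary
    def boundary_faces(self) -> list[tuple[int, int, int, str]]:
        """Faces separating a masked cell from an unmasked (or out-of-grid) cell.

        Returns a list of ``(ix, iy, face_index, label)`` with the face index
        into ``(+x, -x, +y, -y)`` and label epicardium/endocardium by which
        contour the face sits on (outer vs inner rim of the annulus).
        """
        nx, ny = self.grid_shape
        r, _ = self.polar()
        mid = 0.5 * (self.inner_radius + self.outer_radius)
        out = []
        ixs, iys = np.nonzero(self.mask)
        for ix, iy in zip(ixs.tolist(), iys.tolist()):
            for fi, (ox, oy) in enumerate(_FACE_OFFSETS):
                jx, jy = ix + ox, iy + oy
                if 0 <= jx < nx and 0 <= jy < ny and self.mask[jx, jy]:
                    continue
                label = EPICARDIUM if r[ix, iy] >= mid else ENDOCARDIUM
                out.append((ix, iy, fi, label))
        return out

    # ------------------------------------------------------------------ queries
    def contains_point(self, p) -> bool:
        """Whether physical point p lies in a masked cell."""
        ix = int(p[0] / self.cell_size)
        iy = int(p[1] / self.cell_size)
        nx, ny = self.grid_shape
        if not (0 <= ix < nx and 0 <= iy < ny):
            return False
        return bool(self.mask[ix, iy])

    def points_inside(self, pts: np.ndarray, region=None) -> np.ndarray:
        """Vectorized containment test; optionally against one perfusion region."""
        pts = np.atleast_2d(pts)
        idx = np.floor(pts / self.cell_size).astype(int)
        nx, ny = self.grid_shape
        ok = (
            (idx[:, 0] >= 0)
            & (idx[:, 0] < nx)
            & (idx[:, 1] >= 0)
            & (idx[:, 1] < ny)
        )
        res = np.zeros(len(pts), dtype=bool)
        target = self.mask if region is None else self.region_mask(region)
        res[ok] = target[idx[ok, 0], idx[ok, 1]]
        return res

    # ------------------------------------------------------------------ I/O
    def geometry_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "cell_size_mm": self.cell_size,
            "inner_radius_mm": self.inner_radius,
            "outer_radius_mm": self.outer_radius,
            "center_mm": list(self.center),
            "angular_splits_rad": [list(map(float, s)) for s in self.angular_splits],
            "region_names": list(REGION_NAMES),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.geometry_dict(), fh, indent=1)


def default_angular_splits() -> tuple:
    """Equal 120-degree sectors with the RCA territory centered on angle 0.

    Angle 0 points toward +x, i.e. the right side of the slice, where the
    right coronary artery enters; LCX and LAD fill the remaining thirds.
    """
    third = TWO_PI / 3.0
    return (
        (np.pi / 3.0, np.pi / 3.0 + third),          # LCX
        (np.pi / 3.0 + third, np.pi / 3.0 + 2 * third),  # LAD
        (-np.pi / 3.0, np.pi / 3.0),                 # RCA
    )


def build_annulus_domain(
    n_cells: int = 100,
    cell_size_mm: float = 0.25,
    inner_radius: float = 5.0,
    outer_radius: float = 11.0,
    angular_splits: tuple | None = None,
) -> MyocardialDomain:
    """Build the canonical annular slice with three perfusion sectors.

    Parameters use the default study geometry: a 25 mm square at 0.25 mm
    resolution with wall radii 5-11 mm; all overridable.
    """
    if angular_splits is None:
        angular_splits = default_angular_splits()
    if len(angular_splits) != 3:
        raise GeometryError("exactly three angular sectors are required")
    if not (0.0 < inner_radius < outer_radius):
        raise GeometryError(
            f"degenerate annulus: inner={inner_radius}, outer={outer_radius}"
        )
    extent = n_cells * cell_size_mm
    if outer_radius > extent / 2.0 + 1e-12:
        raise GeometryError("outer radius exceeds half the grid extent")

    center = (extent / 2.0, extent / 2.0)
    dom = MyocardialDomain(
        grid_shape=(n_cells, n_cells),
        cell_size=cell_size_mm,
        mask=np.zeros((n_cells, n_cells), dtype=bool),
        perfusion_region=np.full((n_cells, n_cells), REGION_NONE, dtype=np.int8),
        inner_radius=inner_radius,
        outer_radius=outer_radius,
        center=center,
        angular_splits=tuple(angular_splits),
    )
    r, theta = dom.polar()
    dom.mask = (r >= inner_radius) & (r <= outer_radius)
    if not dom.mask.any():
        raise GeometryError("annulus mask is empty at this resolution")
    for i, (a0, a1) in enumerate(angular_splits):
        sel = dom.mask & _in_sector(theta, a0, a1)
        dom.perfusion_region[sel] = i
    # every masked cell must belong to exactly one sector
    if (dom.mask & (dom.perfusion_region == REGION_NONE)).any():
        raise GeometryError("angular splits do not partition the circle")
    return dom


def define_rois(
    domain: MyocardialDomain,
    sector: tuple[float, float],
    radial_band: tuple[float, float],
) -> MyocardialDomain:
    """Set damaged/remote evaluation ROIs without marking fibrosis.

    The damaged ROI is the given sector/band patch; the remote ROI is the
    diametrically opposite patch (same band, sector rotated by pi).
    """
    r, theta = domain.polar()
    b0, b1 = radial_band
    band = (r >= b0) & (r <= b1)
    damaged = domain.mask & band & _in_sector(theta, *sector)
    if not damaged.any():
        raise GeometryError("ROI sector/band does not intersect the annulus")
    remote = domain.mask & band & _in_sector(
        theta, sector[0] + np.pi, sector[1] + np.pi
    )
    domain.roi_damaged = damaged
    domain.roi_remote = remote
    return domain


def define_fibrosis_roi(
    domain: MyocardialDomain,
    sector: tuple[float, float],
    radial_band: tuple[float, float],
) -> MyocardialDomain:
    """Mark a subendocardial fibrotic patch and matching evaluation ROIs.

    The fibrosis mask is the patch of masked cells in the given angular
    sector whose radius falls inside ``radial_band`` (band measured from
    the annulus center, typically the innermost ~30% of the wall).
    ``roi_damaged`` defaults to this patch, ``roi_remote`` to the
    diametrically opposite one.
    """
    define_rois(domain, sector, radial_band)
    domain.fibrosis_mask = domain.roi_damaged.copy()
    return domain


def subendocardial_band(
    domain: MyocardialDomain, wall_fraction: float = 0.3
) -> tuple[float, float]:
    """Radial band covering the innermost ``wall_fraction`` of the wall."""
    w = domain.outer_radius - domain.inner_radius
    return (domain.inner_radius, domain.inner_radius + wall_fraction * w)
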