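"""Extravascular and fibrotic contrast-agent dynamics on the tissue grid.

The myocardium outside the vessels is treated as a porous medium.  The
interstitial concentration Ce obeys a reaction-diffusion balance (no
interstitial advection):

    (1-phi) lam dCe/dt = (1-phi) lam div(De grad Ce) + f
                         - (1-phi) lam ke Ce - g ,

where phi is the intravascular porosity, lam the interstitial fraction of
the extravascular space, f the point source delivered by the mapped
terminal nodes, ke the venous clearance rate and g the adsorption flux
into fibrosis.  On fibrotic cells the trapped concentration Cf obeys

    (1-phi) lam lam_f dCf/dt = g - (1-phi) lam lam_f kf Cf ,
    g = (1-phi) lam lam_f kef Ce ,

a first-order trap with its own slow clearance kf.  Diffusion is a
five-point finite-volume Laplacian on the masked grid; faces toward
unmasked cells or the grid edge carry zero flux, which realizes the
no-flux endocardial/epicardial boundary conditions.  Time stepping is
explicit Euler under the 2D diffusion CFL bound dt <= h^2/(4 De).

All volume bookkeeping assumes a 1 mm slice thickness; concentrations are
in arbitrary units (a.u.), masses in a.u. mm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .domain import MyocardialDomain
from .tree_transport import CFLError


@dataclass(frozen=True)
class TissueParams:
    """Porous-media and kinetic parameters of the tissue compartments."""

    phi: float = 0.10        # intravascular volume fraction
    lam: float = 0.25        # interstitial fraction of extravascular volume
    lam_f: float = 0.0       # fibrotic fraction of the interstitium
    diffusion: float = 1.0e-2  # De, mm^2/s
    k_e: float = 0.007       # interstitium -> venous clearance, 1/s
    k_f: float = 0.0         # fibrosis -> venous clearance, 1/s
    k_ef: float = 0.0        # interstitium -> fibrosis adsorption rate, 1/s
    permeability: float = 1.0  # endothelial P, 1/s

    def __post_init__(self):
        if not (0.0 < self.phi < 1.0):
            raise ValueError("phi must lie in (0, 1)")
        if not (0.0 < self.lam <= 1.0):
            raise ValueError("lam must lie in (0, 1]")
        if not (0.0 <= self.lam_f <= 1.0):
            raise ValueError("lam_f must lie in [0, 1]")


@dataclass
class TissueState:
    """Per-cell extravascular (Ce) and fibrotic (Cf) concentrations."""

    domain: MyocardialDomain
    params: TissueParams
    Ce: np.ndarray = None
    Cf: np.ndarray = None
    _open_faces: tuple = field(default=None, repr=False)

    def __post_init__(self):
        shape = self.domain.grid_shape
        if self.Ce is None:
            self.Ce = np.zeros(shape)
        if self.Cf is None:
            self.Cf = np.zeros(shape)
        m = self.domain.mask
        # open faces for the 5-point Laplacian: both cells masked
        # (stored as float for cheap multiplies in the hot loop)
        self._open_faces = (
            (m[1:, :] & m[:-1, :]).astype(float),  # x faces (i,j)-(i+1,j)
            (m[:, 1:] & m[:, :-1]).astype(float),  # y faces
        )
        self._lap = np.empty(shape)
        self._dx = np.empty((shape[0] - 1, shape[1]))
        self._dy = np.empty((shape[0], shape[1] - 1))

    # ------------------------------------------------------------------ bookkeeping
    @property
    def interstitial_volume_factor(self) -> float:
        """(1-phi)*lam times cell volume: converts Ce to mass per cell."""
        return (1.0 - self.params.phi) * self.params.lam * self.domain.cell_volume

    @property
    def fibrotic_volume_factor(self) -> float:
        return self.interstitial_volume_factor * self.params.lam_f

    def extravascular_mass(self) -> float:
        return float(self.Ce[self.domain.mask].sum()) * self.interstitial_volume_factor

    def fibrotic_mass(self) -> float:
        return float(self.Cf[self.domain.fibrosis_mask].sum()) * self.fibrotic_volume_factor

    def cfl_dt(self) -> float:
        h = self.domain.cell_size
        if self.params.diffusion <= 0:
            return np.inf
        return h * h / (4.0 * self.params.diffusion)

    def laplacian(self) -> np.ndarray:
        """Masked 5-point Laplacian of Ce with zero-flux closed faces (1/mm^2).

        Returns an internal buffer; consume before the next call.
        """
        h2 = self.domain.cell_size**2
        fx, fy = self._open_faces
        lap, dx, dy = self._lap, self._dx, self._dy
        Ce = self.Ce
        np.subtract(Ce[1:, :], Ce[:-1, :], out=dx)
        dx *= fx
        np.subtract(Ce[:, 1:], Ce[:, :-1], out=dy)
        dy *= fy
        lap.fill(0.0)
        lap[:-1, :] += dx
        lap[1:, :] -= dx
        lap[:, :-1] += dy
        lap[:, 1:] -= dy
        lap /= h2
        return lap


def step_tissue(
    state: TissueState,
    source_mass: np.ndarray | None,
    dt: float,
    check_cfl: bool = True,
) -> dict:
    """Advance Ce one explicit step; returns the step's mass budget.

    ``source_mass`` is the contrast mass (a.u. mm^3) delivered by the
    terminal nodes during this step, either as a full per-cell grid or as
    a ``(ix, iy, mass)`` triple of unique mapped cells; venous clearance
    and fibrosis adsorption are integrated from the pre-step state so the
    budget closes exactly.  Cells outside the mask stay at zero: all their
    faces are closed and every reaction is proportional to Ce.
    """
    if check_cfl and dt > state.cfl_dt() * (1 + 1e-12):
        raise CFLError(f"dt={dt} violates the tissue diffusion CFL bound")
    p = state.params
    Ce = state.Ce
    rate = state.laplacian()  # internal buffer, consumed here
    rate *= p.diffusion
    rate -= p.k_e * Ce
    adsorbed = 0.0
    if p.lam_f > 0.0 and p.k_ef > 0.0:
        fib = state.domain.fibrosis_mask
        g_rate = p.lam_f * p.k_ef * Ce[fib]  # g/((1-phi) lam)
        rate[fib] -= g_rate
        adsorbed = float(g_rate.sum()) * dt * state.interstitial_volume_factor
    venous = float(Ce.sum()) * p.k_e * dt * state.interstitial_volume_factor
    Ce_new = Ce + dt * rate
    if source_mass is not None:
        ivf = state.interstitial_volume_factor
        if isinstance(source_mass, tuple):
            ix, iy, mass = source_mass
            Ce_new[ix, iy] += mass / ivf
        else:
            Ce_new += source_mass / ivf
    state.Ce = Ce_new
    return {"venous_mass": venous, "adsorbed_mass": adsorbed}


def step_fibrosis(state: TissueState, dt: float) -> dict:
    """Advance Cf one explicit step (adsorption gain, slow clearance).

    The adsorption gain g is computed from the same pre-step Ce used in
    :func:`step_tissue`, so mass moved out of the interstitium lands in
    the fibrosis compartment exactly.  Call before overwriting Ce, or use
    :func:`step_tissue_and_fibrosis`.
    """
    fib = state.domain.fibrosis_mask
    if not fib.any():
        warnings.warn("step_fibrosis called with an empty fibrosis mask", stacklevel=2)
        return {"fibrotic_venous_mass": 0.0}
    p = state.params
    rate = p.k_ef * state.Ce[fib] - p.k_f * state.Cf[fib]
    venous = float(state.Cf[fib].sum()) * p.k_f * dt * state.fibrotic_volume_factor
    state.Cf[fib] = state.Cf[fib] + dt * rate
    return {"fibrotic_venous_mass": venous}


def step_tissue_and_fibrosis(
    state: TissueState, source_mass: np.ndarray | None, dt: float,
    check_cfl: bool = True,
) -> dict:
    """Coupled explicit step of Ce and Cf from a common pre-step state."""
    budget = {"fibrotic_venous_mass": 0.0}
    if state.params.lam_f > 0.0 and state.domain.fibrosis_mask.any():
        Ce_pre = state.Ce
        p = state.params
        fib = state.domain.fibrosis_mask
        rate = p.k_ef * Ce_pre[fib] - p.k_f * state.Cf[fib]
        budget["fibrotic_venous_mass"] = (
            float(state.Cf[fib].sum()) * p.k_f * dt * state.fibrotic_volume_factor
        )
        state.Cf[fib] = state.Cf[fib] + dt * rate
    budget.update(step_tissue(state, source_mass, dt, check_cfl=check_cfl))
    return budget


def roi_signal(
    state: TissueState, roi: np.ndarray, include_fibrosis: bool = False
) -> float:
    """Mean concentration over an ROI (optionally lam_f-weighted Ce + Cf).

    The fibrosis-weighted variant approximates the late-enhancement MRI
    signal, where trapped contrast contributes in proportion to the
    fibrotic volume fraction.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if not (roi <= state.domain.mask).all():
        raise ValueError("ROI extends outside the myocardial mask")
    sig = state.Ce[roi]
    if include_fibrosis:
        sig = sig + state.params.lam_f * state.Cf[roi]
    return float(sig.mean())
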