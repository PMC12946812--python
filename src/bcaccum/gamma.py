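"""Global gamma-index comparison and landmark target registration error (TRE).

The gamma index combines a dose-difference criterion (percent of the
global maximum of the reference distribution) with a distance-to-agreement
(DTA, mm).  A voxel passes when some point within the search radius of the
evaluated distribution agrees in dose within the criterion after trading
off spatial distance, i.e. gamma <= 1.

Conventions (configurable): global normalization to the reference maximum,
low-dose cutoff 10% of that maximum, search radius 3x DTA, and trilinear
interpolation of the evaluated dose on a sub-voxel displacement lattice
with step DTA/5 per axis.  Gamma is directional: swapping reference and
evaluated changes the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from bcaccum.grids import VoxelGrid


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma comparison settings.

    dose_pct
        Dose criterion as percent of the global reference maximum.
    dta_mm
        Distance-to-agreement in mm.
    cutoff_pct
        Reference voxels below this percent of the maximum are excluded.
    search_factor
        Search radius = search_factor * dta_mm.
    step_divisor
        Sub-voxel search step = dta_mm / step_divisor per axis.
    gamma_cap
        Optional ceiling: stop refining a voxel once its gamma is known to
        exceed this value.  Pass/fail (gamma <= 1) is unaffected for any
        cap >= 1, but reported gamma values above the cap are upper
        bounds, not exact minima.  ``None`` searches exhaustively.
    """

    dose_pct: float = 2.0
    dta_mm: float = 2.0
    cutoff_pct: float = 10.0
    search_factor: float = 3.0
    step_divisor: int = 5
    gamma_cap: float | None = None

    def __post_init__(self):
        if min(self.dose_pct, self.dta_mm, self.cutoff_pct) <= 0:
            raise ValueError("gamma criteria must be positive")
        if self.search_factor < 1.0:
            raise ValueError("search radius must be at least the DTA")
        if self.gamma_cap is not None and self.gamma_cap < 1.0:
            raise ValueError("gamma cap below 1 would corrupt pass/fail decisions")

    @property
    def search_radius_mm(self) -> float:
        return self.search_factor * self.dta_mm

    @property
    def step_mm(self) -> float:
        return self.dta_mm / self.step_divisor


def _displacement_lattice(criteria: GammaCriteria) -> np.ndarray:
    """All displacement vectors (mm) on the search lattice, sorted by length."""
    r = criteria.search_radius_mm
    ax = np.arange(-r, r + 1e-9, criteria.step_mm)
    # make the lattice symmetric around zero even when step does not divide r
    ax = ax - (ax[0] + ax[-1]) / 2.0
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()])
    d2 = np.einsum("ij,ij->i", offs, offs)
    keep = d2 <= r * r + 1e-9
    offs, d2 = offs[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return offs[order]


def gamma_map(
    reference: VoxelGrid,
    evaluated: VoxelGrid,
    criteria: GammaCriteria = GammaCriteria(),
    roi_mask: np.ndarray | None = None,
) -> tuple[VoxelGrid, float]:
    """Per-voxel gamma of ``evaluated`` against ``reference``.

    Returns a grid holding gamma where evaluated (NaN elsewhere) and the
    pass rate in percent.  Voxels of the reference below the low-dose
    cutoff (and outside ``roi_mask`` if given) are excluded.  Lattice
    sample points falling outside the evaluated grid are ignored.

    The search enumerates lattice displacements in order of increasing
    length and stops refining a voxel once the distance term alone exceeds
    its best gamma so far, which is exact for the discrete lattice.
    """
    reference.require_same_geometry(evaluated)
    ref = np.asarray(reference.data, dtype=float)
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValueError("reference maximum must be positive")

    sel = ref >= criteria.cutoff_pct / 100.0 * ref_max
    if roi_mask is not None:
        sel &= np.asarray(roi_mask, dtype=bool)
    idx = np.argwhere(sel)
    if idx.shape[0] == 0:
        raise ValueError("no voxels to evaluate after ROI/cutoff selection")

    dd_abs = criteria.dose_pct / 100.0 * ref_max
    dta = criteria.dta_mm
    spacing = np.asarray(reference.spacing)
    shape = np.asarray(ref.shape)
    ev = np.asarray(evaluated.data, dtype=float)
    ref_vals = ref[sel]

    cap2 = np.inf if criteria.gamma_cap is None else criteria.gamma_cap ** 2
    best = np.full(idx.shape[0], np.inf)
    active = np.arange(idx.shape[0])
    for off in _displacement_lattice(criteria):
        dist2 = float(off @ off) / (dta * dta)
        still = np.minimum(best[active], cap2) > dist2
        active = active[still]
        if active.size == 0:
            break
        coords = idx[active].T + (off / spacing)[:, None]
        inside = np.all((coords >= 0) & (coords <= (shape - 1)[:, None] + 1e-9), axis=0)
        if not np.any(inside):
            continue
        act = active[inside]
        samp = map_coordinates(ev, coords[:, inside], order=1, mode="nearest")
        g2 = ((samp - ref_vals[act]) / dd_abs) ** 2 + dist2
        np.minimum.at(best, act, g2)

    gamma_vals = np.sqrt(best)
    out = np.full(ref.shape, np.nan)
    out[sel] = gamma_vals
    pass_rate = 100.0 * float(np.count_nonzero(gamma_vals <= 1.0)) / gamma_vals.size
    return reference.copy_with(out), pass_rate


def tre(points_a: np.ndarray, points_b: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-point Euclidean distances (mm) and their mean between paired landmarks."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"landmark count/shape mismatch: {a.shape} vs {b.shape}")
    d = np.linalg.norm(a - b, axis=1)
    return d, float(d.mean())
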