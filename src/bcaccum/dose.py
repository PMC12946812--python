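"""Deterministic density-aware dose engine.

A transparent stand-in for a clinical convolution algorithm: each of
``n_beams`` coplanar, equispaced parallel beams deposits

    dose(v) = aperture_weight(v) * exp(-mu_eff * radiological_depth(v))

where radiological depth is the water-equivalent path length (line
integral of relative electron density, mm) from the patient surface to
the voxel along the beam axis, and the aperture weight is the beam's-eye
projection of the PTV plus margin softened by a Gaussian penumbra.  The
beam sum is scaled once, on the planning anatomy, so the median PTV dose
equals the per-fraction prescription; daily recalculations reuse that
scale (fixed machine output), so density changes - e.g. an expanded gas
pocket upstream of the target - translate directly into delivered-dose
changes, the mechanism under study.

There is no scatter kernel, no couch, and no claim of clinical accuracy;
the model is chosen to be simple, strictly deterministic, and
monotonically sensitive to electron density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, map_coordinates, rotate

from bcaccum.grids import VoxelGrid


@dataclass(frozen=True)
class BeamConfig:
    """Coplanar beam arrangement rotating in the (x, y) plane."""

    n_beams: int = 12
    mu_eff_per_mm: float = 0.005
    penumbra_sigma_mm: float = 5.0
    aperture_margin_mm: float = 8.0
    prescription_per_fraction_gy: float = 2.0

    def __post_init__(self):
        if self.n_beams < 1:
            raise ValueError("need at least one beam")
        if self.mu_eff_per_mm < 0:
            raise ValueError("attenuation coefficient must be non-negative")

    @property
    def gantry_angles_deg(self) -> np.ndarray:
        return np.arange(self.n_beams) * 360.0 / self.n_beams


@dataclass
class DoseGrid:
    """Dose in Gy plus the normalization applied to the raw beam sum."""

    grid: VoxelGrid
    scale: float

    @property
    def data(self) -> np.ndarray:
        return self.grid.data


def radiological_depth(red_grid: VoxelGrid, source_point_mm, voxel_index) -> float:
    """Water-equivalent depth (mm) from a source point to a voxel centre.

    Line integral of RED along the straight ray, evaluated by uniform
    sub-voxel stepping (step = half the smallest spacing) with trilinear
    interpolation; RED outside the grid counts as zero.
    """
    spacing = np.asarray(red_grid.spacing)
    src = np.asarray(source_point_mm, dtype=float)
    dst = red_grid.world_coords(np.asarray(voxel_index, dtype=float))[0]
    vec = dst - src
    length = float(np.linalg.norm(vec))
    if length == 0:
        return 0.0
    step = float(spacing.min()) / 2.0
    n = max(int(np.ceil(length / step)), 1)
    t = (np.arange(n) + 0.5) / n
    pts = src[None, :] + t[:, None] * vec[None, :]
    idx = red_grid.index_coords(pts).T
    shape = np.asarray(red_grid.shape)
    inside = np.all((idx >= 0) & (idx <= (shape - 1)[:, None]), axis=0)
    red = np.zeros(n)
    if np.any(inside):
        red[inside] = map_coordinates(np.asarray(red_grid.data, float),
                                      idx[:, inside], order=1)
    return float(red.sum() * (length / n))


def _beam_dose(red: np.ndarray, ptv: np.ndarray, spacing: np.ndarray,
               angle_deg: float, beams: BeamConfig) -> np.ndarray:
    """Single parallel beam travelling along +x after in-plane rotation."""
    red_r = rotate(red, angle_deg, axes=(0, 1), reshape=False, order=1,
                   mode="constant", cval=0.0)
    ptv_r = rotate(ptv.astype(float), angle_deg, axes=(0, 1), reshape=False,
                   order=1, mode="constant", cval=0.0) > 0.5
    # water-equivalent depth: cumulative RED along the beam axis (axis 0),
    # sampled at voxel centres (half-step offset for the entry voxel)
    depth = (np.cumsum(red_r, axis=0) - 0.5 * red_r) * spacing[0]
    # beam's-eye aperture: PTV projection + margin, Gaussian penumbra
    proj = ptv_r.any(axis=0)
    it_y = max(int(round(beams.aperture_margin_mm / spacing[1])), 0)
    it_z = max(int(round(beams.aperture_margin_mm / spacing[2])), 0)
    if proj.any() and max(it_y, it_z) > 0:
        proj = binary_dilation(proj, iterations=max(it_y, it_z))
    ap = gaussian_filter(proj.astype(float),
                         sigma=(beams.penumbra_sigma_mm / spacing[1],
                                beams.penumbra_sigma_mm / spacing[2]))
    dose_r = ap[None, :, :] * np.exp(-beams.mu_eff_per_mm * depth)
    return rotate(dose_r, -angle_deg, axes=(0, 1), reshape=False, order=1,
                  mode="constant", cval=0.0)


def compute_fraction_dose(red_grid: VoxelGrid, beams: BeamConfig,
                          ptv_mask: np.ndarray,
                          scale: float | None = None) -> DoseGrid:
    """Sum the coplanar beams on a RED grid and scale to dose.

    With ``scale=None`` (planning call) the beam sum is normalized so the
    median PTV dose equals the per-fraction prescription, and the factor
    used is recorded on the returned :class:`DoseGrid`.  Passing that
    factor back in recalculates a fraction at fixed machine output, so
    anatomy changes alter the delivered dose instead of being normalized
    away.
    """
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise ValueError("empty PTV mask: cannot aim or normalize the beams")
    red = np.asarray(red_grid.data, dtype=float)
    spacing = np.asarray(red_grid.spacing)
    total = np.zeros_like(red)
    for ang in beams.gantry_angles_deg:
        total += _beam_dose(red, ptv_mask, spacing, ang, beams)
    if scale is None:
        med = float(np.median(total[ptv_mask]))
        if med <= 0:
            raise ValueError("median PTV beam sum is zero; geometry error")
        scale = beams.prescription_per_fraction_gy / med
    dose = np.maximum(total * scale, 0.0)
    return DoseGrid(grid=red_grid.copy_with(dose), scale=float(scale))
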