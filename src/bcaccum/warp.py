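"""Rigid landmark alignment, DVF dose warping, QA gating, and accumulation.

Per-fraction doses live on the daily anatomy; analysis lives on the
planning geometry.  Each fraction is (1) rigidly aligned on bony
landmarks, (2) warped to the planning grid by pull-back sampling of the
deformation vector field (DVF), (3) gated on landmark target
registration error (TRE <= 3 mm) and gamma agreement (2%/2 mm >= 90%)
against the directly recalculated fraction dose, and (4) summed
voxel-wise over the accepted fractions.

The DVF maps planning points to fraction points, so the warped value at
a planning voxel is the trilinear sample of the fraction dose at
``planning point + displacement``; samples falling outside the fraction
grid contribute 0 Gy and are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from bcaccum.gamma import GammaCriteria, gamma_map, tre
from bcaccum.grids import VoxelGrid


# ---------------------------------------------------------------------------
# Rigid alignment
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Six-degree-of-freedom transform ``x -> R x + t`` in world mm."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    residual_rms_mm: float = 0.0

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points_mm) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, self.residual_rms_mm)


def rigid_align(moving_landmarks: np.ndarray, fixed_landmarks: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit mapping moving landmarks onto fixed ones.

    Standard SVD (Kabsch) solution of the orthogonal Procrustes problem
    without scaling; requires >= 3 non-collinear landmark pairs.
    """
    a = np.atleast_2d(np.asarray(moving_landmarks, float))
    b = np.atleast_2d(np.asarray(fixed_landmarks, float))
    if a.shape != b.shape or a.shape[0] < 3 or a.shape[1] != 3:
        raise ValueError("need matching sets of >= 3 landmarks in 3-D")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1e-300):
        raise ValueError("landmarks are collinear or degenerate")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - r @ ca
    res = np.sqrt(np.mean(np.sum((a @ r.T + t - b) ** 2, axis=1)))
    return RigidTransform(r, t, float(res))


# ---------------------------------------------------------------------------
# Dose warping
# ---------------------------------------------------------------------------

def warp_dose(fraction_dose: VoxelGrid, dvf: np.ndarray) -> tuple[VoxelGrid, int]:
    """Pull the fraction dose back onto the planning geometry.

    ``dvf`` has shape ``grid_shape + (3,)`` in mm on the planning
    geometry.  Returns the warped grid and the count of planning voxels
    whose sample point fell outside the fraction grid (those get 0 Gy).
    """
    dvf = np.asarray(dvf, dtype=float)
    if dvf.shape != fraction_dose.shape + (3,):
        raise ValueError(
            f"DVF shape {dvf.shape} does not match dose geometry {fraction_dose.shape}")
    spacing = np.asarray(fraction_dose.spacing)
    shape = np.asarray(fraction_dose.shape)
    idx = np.indices(fraction_dose.shape, dtype=float)
    coords = idx + np.moveaxis(dvf, -1, 0) / spacing[:, None, None, None]
    flat = coords.reshape(3, -1)
    inside = np.all((flat >= 0) & (flat <= (shape - 1)[:, None] + 1e-9), axis=0)
    vals = map_coordinates(np.asarray(fraction_dose.data, float), flat, order=1,
                           mode="constant", cval=0.0)
    vals[~inside] = 0.0
    out = fraction_dose.copy_with(vals.reshape(fraction_dose.shape))
    return out, int(np.count_nonzero(~inside))


# ---------------------------------------------------------------------------
# QA gates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QAGates:
    tre_max_mm: float = 3.0
    # capped gamma: pass/fail identical, failing voxels not refined past 1.25
    gamma_criteria: GammaCriteria = field(
        default_factory=lambda: GammaCriteria(gamma_cap=1.25))
    gamma_pass_min_pct: float = 90.0
    max_retries: int = 1

    def __post_init__(self):
        if min(self.tre_max_mm, self.gamma_pass_min_pct) <= 0:
            raise ValueError("QA thresholds must be positive")


@dataclass
class QAResult:
    passed: bool
    tre_mean_mm: float
    gamma_pass_pct: float
    retries: int = 0
    excluded: bool = False


def _dvf_at_points(dvf: np.ndarray, grid: VoxelGrid, points_mm: np.ndarray) -> np.ndarray:
    idx = grid.index_coords(points_mm).T
    return np.stack([map_coordinates(dvf[..., c], idx, order=1, mode="nearest")
                     for c in range(3)], axis=1)


def qa_check(
    dvf: np.ndarray,
    planning_landmarks: np.ndarray,
    fraction_landmarks: np.ndarray,
    warped_dose: VoxelGrid,
    recalculated_dose: VoxelGrid,
    gates: QAGates = QAGates(),
    roi_mask: np.ndarray | None = None,
    retry_hook=None,
) -> QAResult:
    """Gate one fraction's registration on TRE and gamma agreement.

    TRE maps each planning landmark through the DVF and measures its
    distance to the paired fraction landmark.  Gamma compares the warped
    dose (evaluated) against the directly recalculated fraction dose
    (reference) inside the pelvic ROI.  A failing fraction triggers the
    retry hook (a no-op unless supplied) up to ``max_retries`` times,
    after which it is flagged for exclusion from accumulation.
    """
    retries = 0
    while True:
        mapped = np.atleast_2d(planning_landmarks) + _dvf_at_points(
            dvf, recalculated_dose, planning_landmarks)
        _, tre_mean = tre(mapped, fraction_landmarks)
        _, pass_pct = gamma_map(recalculated_dose, warped_dose,
                                gates.gamma_criteria, roi_mask=roi_mask)
        passed = tre_mean <= gates.tre_max_mm and pass_pct >= gates.gamma_pass_min_pct
        if passed or retry_hook is None or retries >= gates.max_retries:
            return QAResult(passed=passed, tre_mean_mm=float(tre_mean),
                            gamma_pass_pct=float(pass_pct), retries=retries,
                            excluded=not passed)
        dvf, warped_dose = retry_hook(dvf, warped_dose, retries)
        retries += 1


# ---------------------------------------------------------------------------
# Accumulation
# ---------------------------------------------------------------------------

@dataclass
class AccumulatedDose:
    dose: VoxelGrid
    n_fractions: int
    qa_ledger: pd.DataFrame


def accumulate(warped_fraction_doses, qa_results=None) -> AccumulatedDose:
    """Voxel-wise sum of accepted warped fraction doses on one geometry."""
    doses = list(warped_fraction_doses)
    if not doses:
        raise ValueError("nothing to accumulate")
    first = doses[0]
    total = np.zeros(first.shape, dtype=float)
    for d in doses:
        first.require_same_geometry(d)
        total += np.asarray(d.data, float)
    if qa_results is None:
        ledger = pd.DataFrame({"fraction": np.arange(1, len(doses) + 1),
                               "status": "accepted"})
    else:
        ledger = pd.DataFrame([
            {"fraction": t + 1, "tre_mm": q.tre_mean_mm,
             "gamma_pct": q.gamma_pass_pct, "retries": q.retries,
             "status": "accepted" if q.passed else "excluded"}
            for t, q in enumerate(qa_results)])
    return AccumulatedDose(dose=first.copy_with(total), n_fractions=len(doses),
                           qa_ledger=ledger)


def pelvic_roi(body_mask: np.ndarray, ptv_mask: np.ndarray,
               spacing: tuple[float, float, float],
               band_mm: float = 5.0) -> np.ndarray:
    """Body voxels restricted to axial slices intersecting the PTV +/- band."""
    zs = np.nonzero(ptv_mask.any(axis=(0, 1)))[0]
    if zs.size == 0:
        raise ValueError("empty PTV mask")
    pad = int(np.ceil(band_mm / spacing[2]))
    lo = max(int(zs[0]) - pad, 0)
    hi = min(int(zs[-1]) + pad, body_mask.shape[2] - 1)
    roi = np.zeros_like(body_mask, dtype=bool)
    roi[:, :, lo:hi + 1] = body_mask[:, :, lo:hi + 1]
    return roi
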