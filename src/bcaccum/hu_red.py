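"""Three-segment HU to relative-electron-density (RED) calibration.

Daily cone-beam images carry scanner-specific HU biases, so dose
recalculation on them needs a dedicated HU-RED curve.  The curve used here
is a piecewise-linear base calibration multiplied, segment by segment, by
scaling factors for three tissue-equivalent HU ranges:

* air:          -1000 <= HU < -200, default factor 0.995
* soft tissue:   -200 <= HU < 300,  default factor 0.977
* bone:           300 <= HU <= 1500, default factor 0.972

Multiplying segments by different factors creates discontinuities at the
breakpoints; the implementation restores continuity with a linear
cross-fade of the factors over a configurable half-width around each
breakpoint.  HU values are clamped to [-1000, 1500] before lookup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from bcaccum.grids import VoxelGrid

HU_MIN, HU_MAX = -1000.0, 1500.0
#: Segment breakpoints: air / soft tissue at -200 HU, soft tissue / bone at 300 HU.
BREAK_AIR_SOFT = -200.0
BREAK_SOFT_BONE = 300.0

DEFAULT_FACTORS = (0.995, 0.977, 0.972)

#: Base anchors of the underlying (uncorrected) CT calibration.  The exact
#: clinical table is vendor-specific; these follow the standard shape of a
#: CT electron-density calibration and are configurable.
DEFAULT_ANCHORS = (
    (-1000.0, 0.001),
    (-200.0, 0.820),
    (0.0, 1.000),
    (300.0, 1.150),
    (1500.0, 1.850),
)


@dataclass
class HUREDCurve:
    """Piecewise-linear HU-RED calibration with per-segment scaling factors."""

    anchors: tuple = DEFAULT_ANCHORS
    factors: tuple[float, float, float] = DEFAULT_FACTORS
    blend_halfwidth: float = 25.0

    _hu: np.ndarray = field(default=None, repr=False)
    _red: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._hu = np.array([a[0] for a in self.anchors], dtype=float)
        self._red = np.array([a[1] for a in self.anchors], dtype=float)
        if np.any(np.diff(self._hu) <= 0) or np.any(np.diff(self._red) < 0):
            raise ValueError("anchors must be strictly increasing in HU and non-decreasing in RED")
        if len(self.factors) != 3:
            raise ValueError("exactly three segment factors required (air, soft, bone)")
        if any(not (0.0 < f <= 1.2) for f in self.factors):
            raise ValueError("segment factors must lie in (0, 1.2]")
        if self.blend_halfwidth < 0:
            raise ValueError("blend half-width must be non-negative")

    def _base(self, hu: np.ndarray) -> np.ndarray:
        return np.interp(hu, self._hu, self._red)

    def _factor(self, hu: np.ndarray) -> np.ndarray:
        """Segment factor with linear cross-fade around each breakpoint."""
        s_air, s_soft, s_bone = self.factors
        w = self.blend_halfwidth
        f = np.where(hu < BREAK_AIR_SOFT, s_air, np.where(hu < BREAK_SOFT_BONE, s_soft, s_bone))
        if w > 0:
            for brk, lo, hi in ((BREAK_AIR_SOFT, s_air, s_soft), (BREAK_SOFT_BONE, s_soft, s_bone)):
                t = np.clip((hu - (brk - w)) / (2.0 * w), 0.0, 1.0)
                in_band = np.abs(hu - brk) < w
                f = np.where(in_band, lo + t * (hi - lo), f)
        return f

    def __call__(self, hu) -> np.ndarray:
        """RED at the given HU value(s); input clamped to [-1000, 1500]."""
        hu = np.clip(np.asarray(hu, dtype=float), HU_MIN, HU_MAX)
        red = self._base(hu) * self._factor(hu)
        return np.maximum(red, 1e-4)

    # -- serialization -------------------------------------------------

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "anchors": [list(a) for a in self.anchors],
                    "factors": list(self.factors),
                    "blend_halfwidth": self.blend_halfwidth,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "HUREDCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            anchors=tuple(tuple(a) for a in d["anchors"]),
            factors=tuple(d["factors"]),
            blend_halfwidth=float(d["blend_halfwidth"]),
        )

    def sample_csv(self, path: str, step: float = 1.0) -> None:
        """Export the sampled curve as two-column CSV (HU, RED)."""
        hu = np.arange(HU_MIN, HU_MAX + step, step)
        np.savetxt(path, np.column_stack([hu, self(hu)]), delimiter=",", header="hu,red", comments="")


def build_curve(
    factors: tuple[float, float, float] = DEFAULT_FACTORS,
    base_anchors: tuple = DEFAULT_ANCHORS,
    blend_halfwidth: float = 25.0,
) -> HUREDCurve:
    """Construct the three-segment calibration curve and validate monotonicity.

    Raises
    ------
    ValueError
        If the anchors are non-monotone or the factored curve fails to be
        non-decreasing over the supported HU range.
    """
    curve = HUREDCurve(anchors=tuple(tuple(a) for a in base_anchors), factors=tuple(factors),
                       blend_halfwidth=blend_halfwidth)
    hu = np.arange(HU_MIN, HU_MAX + 1.0)
    red = curve(hu)
    if np.any(np.diff(red) < -1e-12):
        raise ValueError("factored curve is not monotone non-decreasing; adjust factors or blend width")
    return curve


def apply_curve(curve: HUREDCurve, hu_grid: VoxelGrid) -> VoxelGrid:
    """Map an HU grid element-wise to RED; geometry is preserved."""
    return hu_grid.copy_with(curve(hu_grid.data))


def derive_segment_factors(paired_dose_pairs) -> tuple[float, float, float]:
    """Recover per-segment scaling factors from paired dose recalculations.

    Each element of ``paired_dose_pairs`` is a triple
    ``(reference_dose, recalculated_dose, hu_grid)`` of
    :class:`VoxelGrid` objects on one geometry.  For each HU segment the
    factor is the mean over in-segment voxels (pooled across pairs) of the
    dose ratio reference/recalculated, i.e. the multiplicative correction
    that nulls the mean dose difference in that segment.  Voxels where the
    recalculated dose is ~0 are excluded.

    Returns ``(s_air, s_soft, s_bone)``.
    """
    segments = [
        (HU_MIN, BREAK_AIR_SOFT),
        (BREAK_AIR_SOFT, BREAK_SOFT_BONE),
        (BREAK_SOFT_BONE, HU_MAX + 1e-9),
    ]
    sums = np.zeros(3)
    counts = np.zeros(3, dtype=np.int64)
    for ref, recalc, hu in paired_dose_pairs:
        ref.require_same_geometry(recalc)
        ref.require_same_geometry(hu)
        valid = recalc.data > 1e-9
        ratio = np.where(valid, ref.data / np.where(valid, recalc.data, 1.0), np.nan)
        hu_clamped = np.clip(hu.data, HU_MIN, HU_MAX)
        for i, (lo, hi) in enumerate(segments):
            sel = valid & (hu_clamped >= lo) & (hu_clamped < hi)
            sums[i] += np.nansum(np.where(sel, ratio, 0.0))
            counts[i] += int(np.count_nonzero(sel))
    if np.any(counts == 0):
        names = np.array(["air", "soft tissue", "bone"])
        raise ValueError(f"no voxels with valid dose in segment(s): {', '.join(names[counts == 0])}")
    return tuple(float(s / c) for s, c in zip(sums, counts))
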