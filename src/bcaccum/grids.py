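"""Volumetric containers shared by every stage of the pipeline.

A :class:`VoxelGrid` is a 3-D scalar field (HU, relative electron density,
or Gy) with per-axis spacing in mm and a world origin; a :class:`LabelMap`
carries integer organ labels on the same geometry.  World coordinates are
``origin + index * spacing`` (mm), indices are 0-based, and masks are
half-open voxel sets: a voxel belongs to a structure when its centre does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Canonical organ label codes used by the synthetic phantoms.
ORGAN_LABELS = {
    "body": 1,
    "ptv": 2,
    "bladder": 3,
    "whole_bowel": 4,
    "bc_gas": 5,
    "rectum": 6,
    "bone": 7,
}


@dataclass
class VoxelGrid:
    """3-D scalar field with geometry.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz)``.
    spacing
        Voxel size per axis in mm.
    origin
        World coordinate of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of a single voxel in cc (1 cc = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_geometry(self, other: "VoxelGrid") -> None:
        if not self.same_geometry(other):
            raise ValueError("voxel grids do not share geometry")

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (n, 3) to world mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def index_coords(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world mm points (n, 3) to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def copy_with(self, data: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(np.asarray(data), self.spacing, self.origin)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine), path)

    @classmethod
    def from_nifti(cls, path: str) -> "VoxelGrid":
        img = nib.load(path)
        aff = img.affine
        spacing = tuple(float(aff[i, i]) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


@dataclass
class LabelMap:
    """Integer organ labels sharing a :class:`VoxelGrid` geometry.

    Labels are stored as independent boolean masks so that structures may
    legally overlap where anatomy requires it (gas lies inside whole bowel,
    everything lies inside body).
    """

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    _shape: tuple[int, int, int] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one shape")
        self._shape = shapes.pop() if shapes else None
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self._shape

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def get(self, name: str, default=None):
        return self.masks.get(name, default)

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def volume_cc(self, name: str) -> float:
        """Structure volume as voxel count times voxel volume."""
        return float(np.count_nonzero(self.masks[name])) * self.voxel_volume_cc

    def as_grid(self, name: str) -> VoxelGrid:
        return VoxelGrid(self.masks[name].astype(np.float64), self.spacing, self.origin)

    def to_nifti(self, path: str) -> None:
        """Write a single coded label volume (later labels win on overlap)."""
        coded = np.zeros(self.shape, dtype=np.int16)
        for name, code in ORGAN_LABELS.items():
            if name in self.masks:
                coded[self.masks[name]] = code
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(coded, aff), path)
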