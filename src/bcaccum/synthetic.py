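"""Synthetic pelvic phantoms and treatment courses with controlled bowel-gas motion.

Clinical course data (planning CT plus 25 daily cone-beam images per
patient) cannot be redistributed, so the pipeline is exercised on
programmatic phantoms.  A phantom is a desk-scale pelvic cross-section:
an elliptical body, bony columns (sacrum analogue plus bilateral femoral
heads), an ellipsoidal PTV, a spherical bladder, a rectal tube carved out
of the PTV, a whole-bowel (WB) region wrapped around the PTV, and
spherical intraluminal gas pockets inside WB adjacent to the PTV.

A fraction anatomy realizes a requested relative change in bowel-cavity
gas volume by rescaling the pocket radii (volume scales exactly with the
cube of the radius) and re-rendering.  The analytic displacement field of
that rescaling - a radial stretch inside each pocket, a volume-preserving
radial push outside, tapered smoothly to zero within a finite influence
radius - is recorded as the ground-truth deformation vector field (DVF)
mapping planning points to fraction points.  Bone never moves, so bony
landmarks are fixed and a perfect registration has zero TRE by
construction.

The generator intentionally does not model CT texture, scatter artifacts,
peristaltic repositioning of bowel loops, or body-contour change; bladder
volume varies within the anatomical-stability cap of the emulated cohort
(<= 5%), and the external contour is held fixed (variation 0, within the
8% cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from bcaccum.grids import LabelMap, VoxelGrid


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

def ptv_semiaxes_for_volume(volume_cc: float,
                            ratios: tuple[float, float, float] = (85.0, 48.0, 68.5)
                            ) -> tuple[float, float, float]:
    """Ellipsoid semi-axes (mm) with the given aspect ratios and target volume."""
    base_vol = 4.0 / 3.0 * np.pi * np.prod(ratios) / 1000.0
    s = (volume_cc / base_vol) ** (1.0 / 3.0)
    return tuple(float(r * s) for r in ratios)


@dataclass(frozen=True)
class GasPocket:
    center_mm: tuple[float, float, float]
    radius_mm: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and HU values of the synthetic pelvis.

    Default organ volumes target the anatomy of the emulated cohort:
    PTV ~1170 cc (clinical range 876-1532 cc), bladder ~246 cc, and a
    bowel-gas reservoir of three pockets (~85 cc) adjacent to the PTV.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)

    body_center_mm: tuple[float, float] = (128.0, 128.0)
    body_semiaxes_mm: tuple[float, float] = (118.0, 100.0)

    ptv_center_mm: tuple[float, float, float] = (128.0, 158.0, 80.0)
    ptv_semiaxes_mm: tuple[float, float, float] = (85.0, 48.0, 68.5)

    bladder_center_mm: tuple[float, float, float] = (128.0, 66.0, 48.0)
    bladder_radius_mm: float = 38.9

    rectum_center_mm: tuple[float, float] = (128.0, 196.0)
    rectum_radius_mm: float = 12.0
    rectum_z_range_mm: tuple[float, float] = (8.0, 88.0)

    wb_center_mm: tuple[float, float, float] = (128.0, 104.0, 116.0)
    wb_semiaxes_mm: tuple[float, float, float] = (96.0, 72.0, 72.0)

    sacrum_center_mm: tuple[float, float] = (128.0, 219.0)
    sacrum_radius_mm: float = 8.0
    femoral_head_centers_mm: tuple = ((36.0, 128.0, 64.0), (220.0, 128.0, 64.0))
    femoral_head_radius_mm: float = 20.0

    gas_pockets: tuple[GasPocket, ...] = (
        GasPocket((170.3, 94.7, 112.3), 18.0),
        GasPocket((86.7, 92.3, 104.9), 18.0),
        GasPocket((126.1, 74.9, 128.7), 18.0),
    )

    hu_gas: float = -950.0
    hu_soft: float = 30.0
    hu_ptv: float = 45.0
    hu_bladder: float = 10.0
    hu_bone: float = 700.0
    hu_air: float = -1000.0
    hu_noise_sd: float = 12.0

    #: taper of the pocket displacement field: full strength to the pocket
    #: surface, fading to zero ``dvf_influence_mm`` beyond it.
    dvf_influence_mm: float = 40.0

    @property
    def landmarks_mm(self) -> np.ndarray:
        """Bony landmarks: sacral-promontory analogue + femoral head centres."""
        sac = (self.sacrum_center_mm[0], self.sacrum_center_mm[1], 104.0)
        return np.array([sac, *self.femoral_head_centers_mm], dtype=float)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the emulated 28-patient, 25-fraction course."""

    n_patients: int = 28
    n_fractions: int = 25
    #: per-patient mean bowel-gas volume change (%), drawn Uniform(lo, hi)
    dv_mean_range: tuple[float, float] = (-5.0, 45.0)
    #: per-fraction Gaussian noise around the patient mean (%)
    dv_fraction_sd: float = 10.0
    #: hard clip keeping requested changes geometrically feasible
    dv_clip: tuple[float, float] = (-30.0, 80.0)
    bladder_variation_cap: float = 5.0
    bladder_variation_sd: float = 1.8
    external_variation_cap: float = 8.0
    seed: int = 0
    spec: PhantomSpec = field(default_factory=PhantomSpec)


@dataclass
class FractionAnatomy:
    """One treatment fraction: HU grid, labels, ground-truth DVF, landmarks."""

    hu_grid: VoxelGrid
    labels: LabelMap
    true_dvf: np.ndarray  # (nx, ny, nz, 3) displacement in mm, planning -> fraction
    landmarks_mm: np.ndarray
    target_dv_bc_pct: float
    bladder_variation_pct: float


# ---------------------------------------------------------------------------
# Rendering helpers
# ---------------------------------------------------------------------------

def _world_axes(spec: PhantomSpec):
    sp = np.asarray(spec.spacing)
    return [np.arange(n) * sp[i] for i, n in enumerate(spec.grid_shape)]


def _coords(spec: PhantomSpec):
    ax = _world_axes(spec)
    return np.meshgrid(*ax, indexing="ij")


def _ellipsoid(xx, yy, zz, center, semi):
    return (((xx - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((zz - center[2]) / semi[2]) ** 2) <= 1.0


def _sphere(xx, yy, zz, center, r):
    return ((xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2) <= r * r


def _render_masks(spec: PhantomSpec, pocket_radii: np.ndarray,
                  bladder_radius: float) -> dict[str, np.ndarray]:
    xx, yy, zz = _coords(spec)
    body = (((xx - spec.body_center_mm[0]) / spec.body_semiaxes_mm[0]) ** 2
            + ((yy - spec.body_center_mm[1]) / spec.body_semiaxes_mm[1]) ** 2) <= 1.0

    rectum = ((((xx - spec.rectum_center_mm[0]) ** 2
                + (yy - spec.rectum_center_mm[1]) ** 2) <= spec.rectum_radius_mm ** 2)
              & (zz >= spec.rectum_z_range_mm[0]) & (zz <= spec.rectum_z_range_mm[1]))

    bone = ((((xx - spec.sacrum_center_mm[0]) ** 2
              + (yy - spec.sacrum_center_mm[1]) ** 2) <= spec.sacrum_radius_mm ** 2))
    for c in spec.femoral_head_centers_mm:
        bone |= _sphere(xx, yy, zz, c, spec.femoral_head_radius_mm)
    bone &= body

    # bone and rectum take precedence over the PTV ellipsoid at shared voxels
    ptv = (_ellipsoid(xx, yy, zz, spec.ptv_center_mm, spec.ptv_semiaxes_mm)
           & ~rectum & ~bone & body)

    bladder = _sphere(xx, yy, zz, spec.bladder_center_mm, bladder_radius) & body

    wb = (_ellipsoid(xx, yy, zz, spec.wb_center_mm, spec.wb_semiaxes_mm)
          & body & ~ptv & ~bladder & ~rectum & ~bone)

    gas = np.zeros_like(body)
    for pocket, r in zip(spec.gas_pockets, pocket_radii):
        if r > 0:
            gas |= _sphere(xx, yy, zz, pocket.center_mm, r)

    return {"body": body, "ptv": ptv, "bladder": bladder, "whole_bowel": wb,
            "bc_gas": gas, "rectum": rectum, "bone": bone}


def _render_hu(spec: PhantomSpec, masks: dict[str, np.ndarray],
               rng: np.random.Generator | None) -> np.ndarray:
    hu = np.full(spec.grid_shape, spec.hu_air, dtype=float)
    hu[masks["body"]] = spec.hu_soft
    hu[masks["ptv"]] = spec.hu_ptv
    hu[masks["bladder"]] = spec.hu_bladder
    hu[masks["rectum"]] = spec.hu_soft
    hu[masks["bone"]] = spec.hu_bone
    hu[masks["bc_gas"]] = spec.hu_gas
    if rng is not None and spec.hu_noise_sd > 0:
        hu[masks["body"]] += rng.normal(0.0, spec.hu_noise_sd,
                                        size=int(masks["body"].sum()))
    return hu


def _validate_geometry(spec: PhantomSpec, masks: dict[str, np.ndarray]) -> None:
    body = masks["body"]
    for name in ("ptv", "bladder", "whole_bowel", "rectum", "bone"):
        if np.any(masks[name] & ~body):
            raise ValueError(f"organ '{name}' extends outside the body contour")
    disjoint = ["ptv", "bladder", "whole_bowel", "rectum", "bone"]
    for i, a in enumerate(disjoint):
        for b in disjoint[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"mandatory organs overlap: '{a}' and '{b}'")
    if np.any(masks["bc_gas"] & ~masks["whole_bowel"]):
        raise ValueError("gas pockets extend outside the whole-bowel region")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def generate_planning_phantom(spec: PhantomSpec = PhantomSpec(),
                              seed: int = 0) -> tuple[VoxelGrid, LabelMap]:
    """Render the planning HU grid and organ label map.

    Raises a geometry error when mandatory organs overlap or leave the
    body.  The same seed yields bit-identical output.
    """
    radii = np.array([p.radius_mm for p in spec.gas_pockets], dtype=float)
    masks = _render_masks(spec, radii, spec.bladder_radius_mm)
    _validate_geometry(spec, masks)
    rng = np.random.default_rng(seed)
    hu = _render_hu(spec, masks, rng)
    grid = VoxelGrid(hu, spec.spacing)
    labels = LabelMap(masks, spec.spacing)
    return grid, labels


def _radial_displacement(xx, yy, zz, center, r0, r1, influence_mm):
    """Displacement (mm, 3 components) of a sphere rescaling r0 -> r1.

    Inside the pocket the map is the linear stretch x -> c + (r1/r0)(x-c);
    outside it is the volume-preserving push rho -> (rho^3 + r1^3 - r0^3)^(1/3),
    multiplied by a smoothstep taper that reaches zero ``influence_mm``
    beyond the original surface so distant anatomy (bone, landmarks) is
    untouched.
    """
    dx = xx - center[0]
    dy = yy - center[1]
    dz = zz - center[2]
    rho = np.sqrt(dx * dx + dy * dy + dz * dz)
    rho_safe = np.where(rho > 1e-9, rho, 1e-9)
    delta3 = r1 ** 3 - r0 ** 3

    u_in = rho * (r1 / r0 - 1.0)
    u_out = np.cbrt(np.maximum(rho ** 3 + delta3, 0.0)) - rho
    u = np.where(rho <= r0, u_in, u_out)

    t = np.clip((rho - r0) / influence_mm, 0.0, 1.0)
    taper = 1.0 - t * t * (3.0 - 2.0 * t)  # smoothstep down from 1 at surface
    u = u * np.where(rho <= r0, 1.0, taper)

    scale = u / rho_safe
    return dx * scale, dy * scale, dz * scale


def generate_fraction(planning_spec: PhantomSpec, target_dv_bc_pct: float,
                      seed: int = 0, bladder_variation_pct: float = 0.0
                      ) -> FractionAnatomy:
    """Realize one fraction with the requested bowel-gas volume change.

    Pocket radii are scaled by ``(1 + dV/100)^(1/3)`` so the analytic gas
    volume changes by exactly the target; the measured (voxelized) volume
    agrees within quantization.  ``bladder_variation_pct`` rescales the
    bladder volume analogously (signed percent).

    Raises
    ------
    ValueError
        If the target is <= -100%, or the expanded pockets no longer fit
        inside the whole-bowel region (infeasible expansion).
    """
    if target_dv_bc_pct <= -100.0:
        raise ValueError("gas volume change must exceed -100%")
    spec = planning_spec
    vol_scale = (1.0 + target_dv_bc_pct / 100.0) ** (1.0 / 3.0)
    r0 = np.array([p.radius_mm for p in spec.gas_pockets], dtype=float)
    r1 = r0 * vol_scale
    b_scale = (1.0 + bladder_variation_pct / 100.0) ** (1.0 / 3.0)
    b0 = spec.bladder_radius_mm
    b1 = b0 * b_scale

    masks = _render_masks(spec, r1, b1)
    # feasibility: expanded gas must stay inside the (unchanged) WB region
    if np.any(masks["bc_gas"] & ~masks["whole_bowel"]):
        raise ValueError(
            f"requested expansion {target_dv_bc_pct:+.1f}% pushes gas outside the whole-bowel region")
    _validate_geometry(spec, masks)

    xx, yy, zz = _coords(spec)
    dvf = np.zeros(spec.grid_shape + (3,), dtype=float)
    for pocket, pr0, pr1 in zip(spec.gas_pockets, r0, r1):
        if abs(pr1 - pr0) < 1e-12:
            continue
        ux, uy, uz = _radial_displacement(xx, yy, zz, pocket.center_mm, pr0, pr1,
                                          spec.dvf_influence_mm)
        dvf[..., 0] += ux
        dvf[..., 1] += uy
        dvf[..., 2] += uz
    if abs(b1 - b0) > 1e-12:
        ux, uy, uz = _radial_displacement(xx, yy, zz, spec.bladder_center_mm, b0, b1,
                                          spec.dvf_influence_mm)
        dvf[..., 0] += ux
        dvf[..., 1] += uy
        dvf[..., 2] += uz

    rng = np.random.default_rng(seed)
    hu = _render_hu(spec, masks, rng)
    return FractionAnatomy(
        hu_grid=VoxelGrid(hu, spec.spacing),
        labels=LabelMap(masks, spec.spacing),
        true_dvf=dvf,
        landmarks_mm=spec.landmarks_mm.copy(),
        target_dv_bc_pct=float(target_dv_bc_pct),
        bladder_variation_pct=float(bladder_variation_pct),
    )


@dataclass
class CourseRecord:
    """One patient's course: planning anatomy plus lazily realizable fractions.

    Fraction anatomies are regenerated on demand from recorded targets
    and seeds (25 dense volumes per patient would not fit in memory for a
    full cohort); ``fraction(t)`` is deterministic.
    """

    patient_id: str
    spec: PhantomSpec
    planning_hu: VoxelGrid
    planning_labels: LabelMap
    fraction_dv_targets: np.ndarray
    fraction_bladder_var: np.ndarray
    fraction_seeds: np.ndarray

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_dv_targets)

    def fraction(self, t: int) -> FractionAnatomy:
        return generate_fraction(self.spec, float(self.fraction_dv_targets[t]),
                                 seed=int(self.fraction_seeds[t]),
                                 bladder_variation_pct=float(self.fraction_bladder_var[t]))


def generate_cohort(config: CohortConfig = CohortConfig()) -> list[CourseRecord]:
    """Draw a cohort of course skeletons under the stability caps.

    Per-fraction gas-volume targets are a patient mean (uniform over the
    configured range) plus fraction noise, clipped to the feasible range;
    bladder variation draws exceeding the 5% cap are resampled so no
    emitted fraction violates it.  The seed fully determines the cohort.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_patients):
        mean_dv = rng.uniform(*config.dv_mean_range)
        dv = np.clip(mean_dv + rng.normal(0.0, config.dv_fraction_sd,
                                          size=config.n_fractions), *config.dv_clip)
        bvar = np.empty(config.n_fractions)
        for t in range(config.n_fractions):
            draw = rng.normal(0.0, config.bladder_variation_sd)
            while abs(draw) >= config.bladder_variation_cap:
                draw = rng.normal(0.0, config.bladder_variation_sd)
            bvar[t] = draw
        seeds = rng.integers(0, 2 ** 31 - 1, size=config.n_fractions)
        plan_seed = int(rng.integers(0, 2 ** 31 - 1))
        hu, labels = generate_planning_phantom(config.spec, seed=plan_seed)
        records.append(CourseRecord(
            patient_id=f"p{i:03d}", spec=config.spec,
            planning_hu=hu, planning_labels=labels,
            fraction_dv_targets=dv, fraction_bladder_var=bvar,
            fraction_seeds=seeds,
        ))
    return records


def spec_with_ptv_volume(spec: PhantomSpec, volume_cc: float) -> PhantomSpec:
    """Copy of ``spec`` with PTV semi-axes rescaled to the target volume."""
    return replace(spec, ptv_semiaxes_mm=ptv_semiaxes_for_volume(
        volume_cc, spec.ptv_semiaxes_mm))
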