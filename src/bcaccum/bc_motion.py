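"""Bowel-cavity (BC) gas segmentation surrogate and the volume-change statistic.

The BC is intraluminal gas within the whole bowel, excluding rectum and
stomach, cropped cranio-caudally to 5 mm above and below the PTV.  On
clinical images this is contoured semi-automatically; on phantoms with
known HU values a threshold stands in: whole-bowel voxels (minus rectum
and stomach labels when present) with HU below -200, the air-segment
boundary of the density calibration, far above typical intraluminal gas
(about -900 HU).

The per-fraction motion statistic is the relative change in BC volume
versus the planning (simulation) scan,

    dV_BC(t) = (V_t - V_sim) / V_sim * 100  (percent),

summarized per patient as the median over the 25 fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bcaccum.grids import LabelMap, VoxelGrid


@dataclass
class BCMask:
    mask: np.ndarray
    volume_cc: float
    mean_hu: float
    band_z_mm: tuple[float, float]


def segment_bc(hu_grid: VoxelGrid, labels: LabelMap,
               gas_threshold_hu: float = -200.0,
               band_margin_mm: float = 5.0) -> BCMask:
    """Threshold-based BC gas mask within the PTV +/- 5 mm band.

    Requires ``whole_bowel`` and ``ptv`` labels; ``rectum`` and
    ``stomach`` are excluded when present.  The cranio-caudal band is the
    PTV bounding range in world mm, inclusive, extended by the margin.
    """
    for req in ("whole_bowel", "ptv"):
        if req not in labels:
            raise ValueError(f"missing required label '{req}'")
    wb = labels["whole_bowel"]
    region = wb.copy()
    for excl in ("rectum", "stomach"):
        if excl in labels:
            region &= ~labels[excl]

    ptv_z = np.nonzero(labels["ptv"].any(axis=(0, 1)))[0]
    if ptv_z.size == 0:
        raise ValueError("PTV label is empty")
    dz = hu_grid.spacing[2]
    z0 = hu_grid.origin[2]
    lo_mm = z0 + ptv_z[0] * dz - band_margin_mm
    hi_mm = z0 + ptv_z[-1] * dz + band_margin_mm
    z_mm = z0 + np.arange(hu_grid.shape[2]) * dz
    in_band = (z_mm >= lo_mm - 1e-9) & (z_mm <= hi_mm + 1e-9)
    region &= in_band[None, None, :]

    mask = region & (np.asarray(hu_grid.data) < gas_threshold_hu)
    vol = float(np.count_nonzero(mask)) * hu_grid.voxel_volume_cc
    mean_hu = float(np.asarray(hu_grid.data)[mask].mean()) if mask.any() else np.nan
    return BCMask(mask=mask, volume_cc=vol, mean_hu=mean_hu, band_z_mm=(lo_mm, hi_mm))


def delta_v_bc(fraction_volumes_cc, sim_volume_cc: float) -> pd.DataFrame:
    """Per-fraction relative BC volume change (%) with the patient median.

    Returns a table with one row per fraction (``fraction``, ``v_cc``,
    ``dv_bc_pct``) carrying the simulation volume and the median change
    as attributes ``sim_volume_cc`` / ``median_dv_bc_pct``.
    """
    v = np.asarray(fraction_volumes_cc, dtype=float)
    if sim_volume_cc <= 0:
        raise ValueError("simulation BC volume must be positive")
    dv = (v - sim_volume_cc) / sim_volume_cc * 100.0
    df = pd.DataFrame({"fraction": np.arange(1, v.size + 1), "v_cc": v,
                       "dv_bc_pct": dv})
    df.attrs["sim_volume_cc"] = float(sim_volume_cc)
    df.attrs["median_dv_bc_pct"] = float(np.median(dv))
    return df
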