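"""Cumulative DVH construction and the endpoint / difference calculus.

Endpoints follow standard DVH notation: ``Dx%`` is the minimum dose
received by the hottest x percent of a structure, ``Dxcc`` the minimum
dose received by the hottest x cc, and ``Vd`` the absolute structure
volume (cc) receiving at least d Gy.  The five primary endpoints of the
analysis are PTV D2%, D50%, D98% and whole-bowel D0.03cc, D150cc; the
toxicity model additionally uses whole-bowel V45.

Differences between a delivered (per-fraction or accumulated) endpoint
and its planned value are expressed both absolutely,
``delta = D_delivered - D_planned`` (Gy), and relatively,
``delta_rel = delta / D_planned * 100`` (percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bcaccum.grids import VoxelGrid

#: Endpoint keys in reporting order.
PTV_ENDPOINTS = ("D2%", "D50%", "D98%")
WB_ENDPOINTS = ("D0.03cc", "D150cc")
ALL_ENDPOINTS = PTV_ENDPOINTS + WB_ENDPOINTS


@dataclass
class DVH:
    """Cumulative dose-volume histogram.

    ``volume_cc[i]`` is the structure volume receiving at least
    ``dose_gy[i]``; the curve starts at the full structure volume at 0 Gy
    and falls to 0 above the maximum dose.
    """

    dose_gy: np.ndarray
    volume_cc: np.ndarray
    structure_volume_cc: float
    bin_width: float

    @property
    def volume_pct(self) -> np.ndarray:
        return self.volume_cc / self.structure_volume_cc * 100.0

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"dose_gy": self.dose_gy, "volume_cc": self.volume_cc}).to_csv(path, index=False)


def compute_dvh(dose_grid: VoxelGrid, mask: np.ndarray, bin_width: float = 0.05) -> DVH:
    """Cumulative DVH from direct voxel sampling of ``dose_grid`` inside ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose_grid.shape:
        raise ValueError("mask and dose grid shapes differ")
    doses = np.asarray(dose_grid.data, dtype=float)[mask]
    if doses.size == 0:
        raise ValueError("empty structure mask")
    vv = dose_grid.voxel_volume_cc
    dmax = float(doses.max())
    n_bins = max(int(np.ceil(dmax / bin_width)) + 1, 2)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(doses, bins=edges)
    # cumulative count of voxels with dose >= left edge of each bin
    cum = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]])
    return DVH(dose_gy=edges, volume_cc=cum * vv, structure_volume_cc=doses.size * vv,
               bin_width=bin_width)


def dose_at_volume(dvh: DVH, q: float, unit: str = "%") -> float:
    """Dose (Gy) to the hottest ``q`` percent (unit '%') or cc (unit 'cc').

    Linear interpolation on the cumulative curve; for sub-voxel volumes
    such as 0.03 cc this interpolates within the top bin.
    """
    if unit == "%":
        v_cc = q / 100.0 * dvh.structure_volume_cc
    elif unit == "cc":
        v_cc = q
    else:
        raise ValueError("unit must be '%' or 'cc'")
    if v_cc < 0 or v_cc > dvh.structure_volume_cc + 1e-9:
        raise ValueError(f"requested volume {v_cc:.3f} cc outside [0, structure volume]")
    # volume_cc is non-increasing in dose; interpolate dose as a function of volume
    v = dvh.volume_cc
    d = dvh.dose_gy
    if v_cc >= v[0]:
        return float(d[0])
    return float(np.interp(-v_cc, -v, d))


def volume_at_dose(dvh: DVH, dose_gy: float) -> float:
    """Absolute structure volume (cc) receiving at least ``dose_gy``."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    if dose_gy >= dvh.dose_gy[-1]:
        return 0.0
    return float(np.interp(dose_gy, dvh.dose_gy, dvh.volume_cc))


def endpoint_set(ptv_dvh: DVH, wb_dvh: DVH) -> dict[str, float]:
    """The five primary endpoints plus whole-bowel V45 (cc)."""
    eps = {
        "D2%": dose_at_volume(ptv_dvh, 2.0, "%"),
        "D50%": dose_at_volume(ptv_dvh, 50.0, "%"),
        "D98%": dose_at_volume(ptv_dvh, 98.0, "%"),
        "D0.03cc": dose_at_volume(wb_dvh, 0.03, "cc"),
        "D150cc": dose_at_volume(wb_dvh, min(150.0, wb_dvh.structure_volume_cc), "cc"),
        "V45cc": volume_at_dose(wb_dvh, 45.0),
    }
    return eps


def diffs(planned: dict[str, float], other: dict[str, float]) -> pd.DataFrame:
    """Absolute (Gy) and relative (%) endpoint differences, delivered minus planned."""
    keys = [k for k in planned if k in other and k != "V45cc"]
    if set(planned) - {"V45cc"} != set(other) - {"V45cc"}:
        raise ValueError("endpoint keys differ between planned and delivered sets")
    rows = []
    for k in keys:
        delta = other[k] - planned[k]
        rows.append({"endpoint": k, "planned": planned[k], "delivered": other[k],
                     "delta_gy": delta, "delta_pct": delta / planned[k] * 100.0})
    return pd.DataFrame(rows)


def _bootstrap_median_ci(values: np.ndarray, n_boot: int, rng: np.random.Generator,
                         alpha: float = 0.05) -> tuple[float, float]:
    boots = np.median(rng.choice(values, size=(n_boot, values.size), replace=True), axis=1)
    return (float(np.quantile(boots, alpha / 2)), float(np.quantile(boots, 1 - alpha / 2)))


#: Exceedance thresholds reported per endpoint: relative (%) for PTV
#: metrics, absolute (Gy) for whole-bowel metrics.
DEFAULT_THRESHOLDS = {
    "D2%": [("delta_pct", 1.0), ("delta_pct", 2.0), ("delta_pct", 3.0)],
    "D50%": [("delta_pct", 1.0), ("delta_pct", 2.0), ("delta_pct", 3.0)],
    "D98%": [("delta_pct", 1.0), ("delta_pct", 2.0), ("delta_pct", 3.0)],
    "D0.03cc": [("delta_gy", 0.5), ("delta_gy", 1.0), ("delta_gy", 2.0), ("delta_gy", 3.0)],
    "D150cc": [("delta_gy", 0.5), ("delta_gy", 1.0), ("delta_gy", 2.0), ("delta_gy", 3.0)],
}


def cohort_summary(per_patient: pd.DataFrame, thresholds: dict | None = None,
                   n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Cohort table of median endpoint deviations with exceedance counts.

    ``per_patient`` holds one row per patient per endpoint with columns
    ``patient``, ``endpoint``, ``delta_gy``, ``delta_pct``.  For each
    endpoint the table reports the cohort median of both difference
    scales with percentile-bootstrap 95% CIs, and the number of patients
    whose absolute deviation meets each threshold.
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    rng = np.random.default_rng(seed)
    rows = []
    for ep, grp in per_patient.groupby("endpoint", sort=False):
        dg = grp["delta_gy"].to_numpy(float)
        dp = grp["delta_pct"].to_numpy(float)
        n = dg.size
        ci_g = _bootstrap_median_ci(dg, n_boot, rng)
        ci_p = _bootstrap_median_ci(dp, n_boot, rng)
        for kind, thr in thresholds.get(ep, []):
            vals = dg if kind == "delta_gy" else dp
            count = int(np.count_nonzero(np.abs(vals) >= thr))
            rows.append({
                "endpoint": ep, "n": n,
                "median_delta_gy": float(np.median(dg)),
                "delta_gy_ci_lo": ci_g[0], "delta_gy_ci_hi": ci_g[1],
                "median_delta_pct": float(np.median(dp)),
                "delta_pct_ci_lo": ci_p[0], "delta_pct_ci_hi": ci_p[1],
                "threshold": f"|{'Δ' if kind == 'delta_gy' else 'δ'}| ≥ {thr:g}"
                             f"{' Gy' if kind == 'delta_gy' else '%'}",
                "n_exceeding": count,
                "frac_exceeding_pct": 100.0 * count / n,
            })
    return pd.DataFrame(rows)
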