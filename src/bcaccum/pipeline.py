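"""End-to-end course simulation: generate, calibrate, dose, warp, accumulate, analyze.

``run_course`` drives the full chain on a synthetic cohort and emits the
analysis tables as CSV plus a JSON manifest of seeds and settings:

1. planning phantom + planning fraction dose (fixes the machine output);
2. per fraction: anatomy with its bowel-gas volume change, HU->RED,
   dose recalculation at fixed output, pull-back warp with the
   ground-truth DVF (optionally perturbed), TRE + gamma QA gates;
3. voxel-wise accumulation over accepted fractions;
4. DVH endpoints and planned-vs-delivered differences (per-fraction
   medians and accumulated), bowel-gas volume series, association
   statistics, and the V45-based NTCP comparison.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bcaccum import __version__
from bcaccum.bc_motion import delta_v_bc, segment_bc
from bcaccum.dose import BeamConfig, compute_fraction_dose
from bcaccum.dvh import ALL_ENDPOINTS, cohort_summary, compute_dvh, diffs, endpoint_set
from bcaccum.gamma import GammaCriteria, gamma_map
from bcaccum.hu_red import HUREDCurve, apply_curve, build_curve
from bcaccum.ntcp import NTCPModel, TriageBands, classify_band, compare_planned_accumulated
from bcaccum.stats import build_assoc_table
from bcaccum.synthetic import CohortConfig, GasPocket, PhantomSpec, generate_cohort
from bcaccum.warp import QAGates, accumulate, pelvic_roi, qa_check, warp_dose


@dataclass
class RunConfig:
    """Serializable configuration of a full synthetic course run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    beams: BeamConfig = field(default_factory=BeamConfig)
    gates: QAGates = field(default_factory=QAGates)
    curve: HUREDCurve = field(default_factory=HUREDCurve)
    ntcp_model: NTCPModel = field(default_factory=NTCPModel)
    bands: TriageBands = field(default_factory=TriageBands)
    stats_seed: int = 0
    n_boot: int = 2000
    #: amplitude (mm) of a uniform DVF perturbation exercising the QA gates
    dvf_noise_mm: float = 0.0
    run_qa: bool = True

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_dict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return _from_dict(cls, yaml.safe_load(fh))


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)
                if not f.name.startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(o) for o in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


_NESTED_FIELDS = {
    "cohort": CohortConfig, "beams": BeamConfig, "gates": QAGates,
    "curve": HUREDCurve, "ntcp_model": NTCPModel, "bands": TriageBands,
    "gamma_criteria": GammaCriteria, "spec": PhantomSpec,
}


def _from_dict(cls, d):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name.startswith("_") or f.name not in d:
            continue
        v = d[f.name]
        sub = _NESTED_FIELDS.get(f.name)
        if sub is not None and isinstance(v, dict):
            kwargs[f.name] = _from_dict(sub, v)
        elif f.name == "gas_pockets":
            kwargs[f.name] = tuple(
                GasPocket(tuple(p["center_mm"]), p["radius_mm"]) for p in v)
        elif f.name == "anchors":
            kwargs[f.name] = tuple(tuple(a) for a in v)
        elif isinstance(v, list):
            kwargs[f.name] = _tuplify(v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


def _tuplify(v):
    return tuple(_tuplify(x) for x in v) if isinstance(v, list) else v


def _perturb_dvf(dvf: np.ndarray, amplitude_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Rigid offset in a random direction, magnitude uniform in [0, amplitude]."""
    if amplitude_mm <= 0:
        return dvf
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return dvf + (rng.uniform(0.0, amplitude_mm) * direction)[None, None, None, :]


def run_course(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full synthetic course and write all report tables.

    Returns a manifest dict (also written to ``manifest.json``) naming
    every emitted file; tables mirror the clinical report layout:
    per-fraction and accumulated endpoint deviation summaries, the
    association table, the NTCP comparison, and the per-fraction QA
    ledger.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curve = build_curve(config.curve.factors, config.curve.anchors,
                        config.curve.blend_halfwidth)
    records = generate_cohort(config.cohort)
    nfx = config.cohort.n_fractions
    rng = np.random.default_rng(config.cohort.seed + 1)

    qa_rows, frac_rows, pat_rows, v45_rows = [], [], [], []
    frac_diff_rows = []

    for rec in records:
        labels = rec.planning_labels
        red_plan = apply_curve(curve, rec.planning_hu)
        plan_frac_dose = compute_fraction_dose(red_plan, config.beams, labels["ptv"])
        planned_course = plan_frac_dose.grid.copy_with(plan_frac_dose.data * nfx)
        dvh_ptv = compute_dvh(planned_course, labels["ptv"])
        dvh_wb = compute_dvh(planned_course, labels["whole_bowel"])
        planned_eps = endpoint_set(dvh_ptv, dvh_wb)
        bc_sim = segment_bc(rec.planning_hu, labels)
        roi = pelvic_roi(labels["body"], labels["ptv"], rec.planning_hu.spacing)

        warped_doses, qa_results, bc_vols = [], [], []
        for t in range(nfx):
            fa = rec.fraction(t)
            red = apply_curve(curve, fa.hu_grid)
            fdose = compute_fraction_dose(red, config.beams, fa.labels["ptv"],
                                          scale=plan_frac_dose.scale)
            dvf = _perturb_dvf(fa.true_dvf, config.dvf_noise_mm, rng)
            warped, n_out = warp_dose(fdose.grid, dvf)
            if config.run_qa:
                qa = qa_check(dvf, rec.spec.landmarks_mm, fa.landmarks_mm,
                              warped, fdose.grid, config.gates, roi_mask=roi)
            else:
                from bcaccum.warp import QAResult
                qa = QAResult(passed=True, tre_mean_mm=0.0, gamma_pass_pct=100.0)
            qa_rows.append({"patient": rec.patient_id, "fraction": t + 1,
                            "tre_mm": qa.tre_mean_mm, "gamma_pct": qa.gamma_pass_pct,
                            "retries": qa.retries, "out_of_grid_voxels": n_out,
                            "status": "accepted" if qa.passed else "excluded"})
            bc = segment_bc(fa.hu_grid, fa.labels)
            bc_vols.append(bc.volume_cc)
            if qa.passed:
                warped_doses.append(warped)
                qa_results.append(qa)
            # per-fraction delivered endpoints, scaled to course dose for
            # comparability with the planned course DVH
            wf = warped.copy_with(warped.data * nfx)
            f_eps = endpoint_set(compute_dvh(wf, labels["ptv"]),
                                 compute_dvh(wf, labels["whole_bowel"]))
            frow = {"patient": rec.patient_id, "fraction": t + 1}
            for ep in ALL_ENDPOINTS:
                frow[f"delta_{ep}"] = f_eps[ep] - planned_eps[ep]
            frac_rows.append(frow)

        if not warped_doses:
            raise RuntimeError(
                f"every fraction of {rec.patient_id} failed QA; nothing to accumulate")
        acc = accumulate(warped_doses, qa_results)
        acc_eps = endpoint_set(compute_dvh(acc.dose, labels["ptv"]),
                               compute_dvh(acc.dose, labels["whole_bowel"]))
        series = delta_v_bc(bc_vols, bc_sim.volume_cc)
        for t in range(nfx):
            frac_rows[-nfx + t]["dv_bc_pct"] = series["dv_bc_pct"].iloc[t]

        prow = {"patient": rec.patient_id,
                "median_dv_bc_pct": series.attrs["median_dv_bc_pct"],
                "n_accepted": acc.n_fractions}
        for ep in ALL_ENDPOINTS:
            prow[f"delta_{ep}"] = acc_eps[ep] - planned_eps[ep]
            prow[f"planned_{ep}"] = planned_eps[ep]
            prow[f"accumulated_{ep}"] = acc_eps[ep]
        pat_rows.append(prow)
        v45_rows.append({"patient": rec.patient_id,
                         "v45_planned": planned_eps["V45cc"],
                         "v45_accumulated": acc_eps["V45cc"],
                         "stratum": classify_band(acc_eps["V45cc"], config.bands)})
        d = diffs(planned_eps, acc_eps)
        d.insert(0, "patient", rec.patient_id)
        frac_diff_rows.append(d)

    patient_df = pd.DataFrame(pat_rows)
    fraction_df = pd.DataFrame(frac_rows)
    qa_df = pd.DataFrame(qa_rows)
    v45_df = pd.DataFrame(v45_rows)
    acc_diffs = pd.concat(frac_diff_rows, ignore_index=True)

    # per-fraction deviations summarized by the within-patient median
    med_rows = []
    for pid, grp in fraction_df.groupby("patient", sort=False):
        planned = {ep: patient_df.loc[patient_df.patient == pid,
                                      f"planned_{ep}"].iloc[0] for ep in ALL_ENDPOINTS}
        for ep in ALL_ENDPOINTS:
            dmed = float(grp[f"delta_{ep}"].median())
            med_rows.append({"patient": pid, "endpoint": ep, "delta_gy": dmed,
                             "delta_pct": dmed / planned[ep] * 100.0})
    frac_summary = cohort_summary(pd.DataFrame(med_rows), n_boot=config.n_boot,
                                  seed=config.stats_seed)

    acc_rows = acc_diffs.rename(columns={"delta_gy": "delta_gy", "delta_pct": "delta_pct"})
    acc_summary = cohort_summary(acc_rows[["patient", "endpoint", "delta_gy", "delta_pct"]],
                                 n_boot=config.n_boot, seed=config.stats_seed + 1)

    if len(patient_df) >= 4:
        assoc = build_assoc_table(patient_df, fraction_df, n_boot=config.n_boot,
                                  seed=config.stats_seed + 2)
    else:
        assoc = pd.DataFrame()
    ntcp_table = compare_planned_accumulated(v45_df, config.ntcp_model)

    files = {
        "qa_ledger": "qa_ledger.csv", "patient_endpoints": "patient_endpoints.csv",
        "fraction_endpoints": "fraction_endpoints.csv",
        "fraction_summary": "fraction_summary.csv",
        "accumulated_summary": "accumulated_summary.csv",
        "association": "association.csv", "ntcp": "ntcp_comparison.csv",
        "v45": "v45_per_patient.csv",
    }
    qa_df.to_csv(outdir / files["qa_ledger"], index=False)
    patient_df.to_csv(outdir / files["patient_endpoints"], index=False)
    fraction_df.to_csv(outdir / files["fraction_endpoints"], index=False)
    frac_summary.to_csv(outdir / files["fraction_summary"], index=False)
    acc_summary.to_csv(outdir / files["accumulated_summary"], index=False)
    assoc.to_csv(outdir / files["association"], index=False)
    ntcp_table.to_csv(outdir / files["ntcp"], index=False)
    v45_df.to_csv(outdir / files["v45"], index=False)

    manifest = {"version": __version__, "config": _to_dict(config), "files": files}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def validate_calibration(hu_pairs, dose_pairs=None,
                         criteria: GammaCriteria = GammaCriteria()) -> dict:
    """Calibration validation report: mean |dHU| and gamma pass rate.

    ``hu_pairs`` yields ``(reference_hu, evaluated_hu)`` grid pairs for
    the HU-agreement statistic; ``dose_pairs`` (defaults to recomputing
    gamma on the HU pairs shifted by +1000 so intensities are
    non-negative) yields dose grid pairs for the 2%/2 mm gamma pass rate
    of evaluated vs reference.
    """
    errs = []
    hu_pairs = list(hu_pairs)
    for ref, ev in hu_pairs:
        ref.require_same_geometry(ev)
        errs.append(float(np.mean(np.abs(ref.data - ev.data))))
    if dose_pairs is None:
        dose_pairs = [(r.copy_with(r.data + 1000.0), e.copy_with(e.data + 1000.0))
                      for r, e in hu_pairs]
    rates = [gamma_map(r, e, criteria)[1] for r, e in dose_pairs]
    return {"mean_abs_hu_error": float(np.mean(errs)),
            "per_pair_abs_hu_error": errs,
            "gamma_pass_pct_mean": float(np.mean(rates)),
            "per_pair_gamma_pass_pct": rates}
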