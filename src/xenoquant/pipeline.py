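"""Stage glue: calibrate, quantify, validate, assess, summarize, run.

Each stage is a pure function DataFrame(s) -> DataFrame(s); ``run_pipeline``
chains them in order, writes every report as a delimited table, and records
the single seed in a machine-readable run manifest.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import calibration as cal
from . import cohort, exposure, quantitation, simulate, validation
from .io import write_peak_table, write_table
from .types import AnalyteSpec, CalibrationCurve, SensitivityEstimate, Status

log = logging.getLogger("xenoquant")


def calibrate_stage(
    peaks: pd.DataFrame, panel: Sequence[AnalyteSpec]
) -> tuple[dict, dict, dict, pd.DataFrame]:
    """Fit matrix and solvent curves, SSE and LOD/LOQ per panel analyte.

    Returns (matrix curves, solvent curves, sensitivities, curve report).
    """
    if {"serum", "plasma"} <= set(peaks["matrix"].unique()):
        log.warning("serum and plasma both present; plasma is treated as serum "
                    "for calibration lookup")
    is_map = {s.name: s.internal_standard for s in panel if s.internal_standard}
    peaks = cal.normalize_by_is(peaks, is_map)
    matrix_curves: dict[str, CalibrationCurve] = {}
    solvent_curves: dict[str, CalibrationCurve] = {}
    sensitivities: dict[str, SensitivityEstimate] = {}
    report = []
    for spec in panel:
        sub = peaks[peaks["analyte"] == spec.name]
        mat = sub[sub["role"] == "calibrant"]
        sol = sub[sub["role"] == "solvent_calibrant"]
        if len(mat) == 0:
            log.warning("no calibrants for %s; skipping", spec.name)
            continue
        used_is = spec.internal_standard is not None
        mcurve = cal.fit_calibration(
            list(zip(mat["nominal_conc"], mat["response"])),
            analyte=spec.name, matrix=spec.calibration_matrix, used_is=used_is,
        )
        matrix_curves[spec.name] = mcurve
        row = {
            "analyte": spec.name, "matrix": spec.calibration_matrix,
            "slope": mcurve.slope, "intercept": mcurve.intercept, "r2": mcurve.r2,
            "range_min": mcurve.range_min, "range_max": mcurve.range_max,
            "used_is": used_is, "sse_pct": np.nan,
        }
        if len(sol) > 0:
            scurve = cal.fit_calibration(
                list(zip(sol["nominal_conc"], sol["response"])),
                analyte=spec.name, matrix="solvent", used_is=used_is,
            )
            solvent_curves[spec.name] = scurve
            row["sse_pct"] = cal.compute_sse(mcurve, scurve)
        if mat["noise"].notna().any():
            sens = cal.estimate_lod_loq(mat, mcurve, spec.name, spec.calibration_matrix)
            sensitivities[spec.name] = sens
            row.update(lod=sens.lod, loq=sens.loq, sens_method=sens.method)
        report.append(row)
    return matrix_curves, solvent_curves, sensitivities, pd.DataFrame(report)


def contamination_stage(
    peaks: pd.DataFrame,
    solvent_curves: dict,
    panel: Sequence[AnalyteSpec],
) -> dict[str, float]:
    """System-blank contamination per flagged analyte via solvent regression."""
    is_map = {s.name: s.internal_standard for s in panel if s.internal_standard}
    peaks = cal.normalize_by_is(peaks, is_map)
    out: dict[str, float] = {}
    for spec in panel:
        blanks = peaks[(peaks["analyte"] == spec.name) & (peaks["role"] == "system_blank")]
        scurve = solvent_curves.get(spec.name)
        if scurve is None or len(blanks) == 0:
            if spec.blank_correct:
                raise ValueError(f"blank correction flagged for {spec.name} "
                                 "but no solvent curve or blanks available")
            continue
        if spec.blank_correct and len(blanks) < 3:
            raise ValueError(f"fewer than 3 system blanks for flagged analyte {spec.name}")
        out[spec.name] = quantitation.blank_contamination(blanks, scurve)
    return out


def quantify_stage(
    peaks: pd.DataFrame,
    matrix_curves: dict,
    sensitivities: dict,
    panel: Sequence[AnalyteSpec],
    recoveries: Optional[dict[str, float]] = None,
    contamination: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Quantify unknown-role rows: invert, blank-subtract, recover, censor."""
    is_map = {s.name: s.internal_standard for s in panel if s.internal_standard}
    unknowns = cal.normalize_by_is(peaks[peaks["role"] == "unknown"], is_map)
    flagged = {s.name for s in panel if s.blank_correct}
    results = quantitation.quantify_unknowns(unknowns, matrix_curves, sensitivities)
    if contamination:
        # keep flagged analytes plus any unflagged one whose blank level is
        # material (above its LOD) — those get the contamination warning
        material = {
            a: v for a, v in contamination.items()
            if a in flagged or (a in sensitivities and v > sensitivities[a].lod)
        }
        results = quantitation.blank_correct(results, material, flagged)
        results = quantitation.recensor(results, sensitivities)
    if recoveries:
        for i, rec in results.iterrows():
            if rec["analyte"] in recoveries and rec["status"] != Status.above_range.value:
                sens = sensitivities[rec["analyte"]]
                snr = rec["snr"] if np.isfinite(rec["snr"]) else None
                conc, flag = quantitation.apply_recovery_rule(
                    rec["conc"], recoveries[rec["analyte"]], sens.loq, snr
                )
                results.at[i, "conc"] = conc
                results.at[i, "recovery_corrected"] = flag
    return results


def validate_stage(
    peaks: pd.DataFrame,
    matrix_curves: dict,
    sensitivities: dict,
    panel: Sequence[AnalyteSpec],
    contamination: Optional[dict[str, float]] = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Validation metrics per analyte/level and average recoveries.

    Spike concentrations are measured through the matrix curve (no recovery
    correction — recovery is what is being estimated) and blank-corrected
    with the same system contamination as the unknowns.
    """
    is_map = {s.name: s.internal_standard for s in panel if s.internal_standard}
    normalized = cal.normalize_by_is(peaks, is_map)
    spikes = normalized[normalized["role"] == "spike"]
    flagged = {s.name for s in panel if s.blank_correct}
    rows = []
    for rec in spikes.itertuples(index=False):
        curve = matrix_curves.get(rec.analyte)
        if curve is None:
            continue
        conc = quantitation.invert_calibration(rec.response, curve)
        if contamination and rec.analyte in flagged:
            conc = max(conc - contamination.get(rec.analyte, 0.0), 0.0)
        rows.append({"analyte": rec.analyte, "nominal_conc": rec.nominal_conc,
                     "day": rec.day, "batch": rec.batch, "conc": conc})
    measured = pd.DataFrame(rows)
    if len(measured) == 0:
        return pd.DataFrame(), {}
    main = measured[measured["batch"] != "rep"]
    repeats = measured[measured["batch"] == "rep"]
    records = validation.validate_spikes(main, repeats if len(repeats) else None)
    # attach linearity and selectivity; the selectivity threshold references
    # the fitted response at the lowest reportable level (the LOQ, or the
    # lowest calibrant if above it) — predicted from the curve, so a single
    # noisy low-level injection does not destabilise the screen
    sel = {}
    for spec in panel:
        sub = normalized[normalized["analyte"] == spec.name]
        mb = sub[sub["role"] == "matrix_blank"]["response"]
        sb = sub[sub["role"] == "system_blank"]["response"]
        curve = matrix_curves.get(spec.name)
        if len(mb) >= 3 and len(sb) >= 3 and curve is not None:
            level = curve.range_min
            if spec.name in sensitivities:
                level = max(level, sensitivities[spec.name].loq)
            lowest = curve.slope * level + curve.intercept
            sel[spec.name] = validation.check_selectivity(mb, sb, lowest)
    records["r2"] = records["analyte"].map(
        {a: c.r2 for a, c in matrix_curves.items()}
    )
    records["selectivity_ok"] = records["analyte"].map(sel)
    records["lod"] = records["analyte"].map(
        {a: s.lod for a, s in sensitivities.items()}
    )
    records["loq"] = records["analyte"].map(
        {a: s.loq for a, s in sensitivities.items()}
    )
    verdicts = records.apply(lambda r: validation.evaluate_analyte(r.to_dict()), axis=1)
    records["criteria"] = [json.dumps(v[0]) for v in verdicts]
    records["fulfils_all"] = [v[1] for v in verdicts]
    # average recovery per analyte across both levels and all days, as a fraction
    recoveries = (
        records.groupby("analyte")["recovery_pct"].mean().div(100.0).clip(upper=1.2)
    ).to_dict()
    return records, recoveries


def summarize_stage(
    results: pd.DataFrame,
    sensitivities: dict,
    longitudinal: Optional[pd.DataFrame] = None,
    cohort_label: str = "cohort",
) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    det_rows, q_rows = [], []
    for analyte, grp in results.groupby("analyte"):
        summ = cohort.detection_summary(grp, cohort_label)
        if summ is None:
            continue
        summ["analyte"] = analyte
        det_rows.append(summ)
        sens = sensitivities.get(analyte)
        if sens is not None:
            try:
                q1, med, q3 = cohort.distribution_summary(grp, sens.loq)
                q_rows.append({"analyte": analyte, "q1": q1, "median": med, "q3": q3})
            except ValueError:
                pass
    out["detection_summary"] = pd.DataFrame(det_rows)
    out["quartiles"] = pd.DataFrame(q_rows)
    if longitudinal is not None and longitudinal["analyte"].nunique() >= 2:
        corr, nmat = cohort.correlation_matrix(longitudinal)
        out["correlation"] = corr.reset_index(names="analyte")
        out["correlation_n"] = nmat.reset_index(names="analyte")
    return out


def run_pipeline(
    outdir: str,
    seed: int = 0,
    panel: Optional[Sequence[AnalyteSpec]] = None,
    design: Optional[dict] = None,
    n_unknowns: int = 20,
    n_days: int = 90,
) -> dict:
    """Run simulate -> calibrate -> quantify -> validate -> assess -> summarize.

    All randomness flows from ``seed`` (per-stage substreams derived from
    it). Writes every report under ``outdir`` and returns the manifest.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sim_seed, long_seed = int(rng.integers(2**31)), int(rng.integers(2**31))

    if panel is None:
        panel, truths, profiles = simulate.demo_inputs()
    else:
        _, truths, profiles = simulate.demo_inputs()
    design = {**{"unknowns": n_unknowns}, **(design or {})}
    peaks, manifest = simulate.generate_batch(panel, truths, design, seed=sim_seed)
    write_peak_table(peaks, out / "peaks.csv")
    longitudinal = simulate.generate_longitudinal(
        profiles, n_days=n_days, sampling_gaps=True, seed=long_seed
    )
    write_table(longitudinal, out / "longitudinal.csv")

    matrix_curves, solvent_curves, sensitivities, curve_report = calibrate_stage(peaks, panel)
    write_table(curve_report, out / "calibration.csv")

    contamination = contamination_stage(peaks, solvent_curves, panel)
    val_records, recoveries = validate_stage(
        peaks, matrix_curves, sensitivities, panel, contamination
    )
    write_table(val_records, out / "validation.csv")

    results = quantify_stage(
        peaks, matrix_curves, sensitivities, panel, recoveries, contamination
    )
    write_table(results, out / "quantitation.csv")

    quant_by_analyte = {
        a: (grp, sensitivities[a].loq)
        for a, grp in results.groupby("analyte") if a in sensitivities
    }
    assessment = exposure.build_assessment_table(
        quant_by_analyte=quant_by_analyte, panel=panel
    )
    write_table(assessment, out / "exposure.csv")

    summaries = summarize_stage(results, sensitivities, longitudinal)
    for name, df in summaries.items():
        write_table(df, out / f"{name}.csv")

    run_manifest = {
        "seed": int(seed),
        "stages": ["simulate", "calibrate", "quantify", "validate", "assess", "summarize"],
        "outputs": sorted(p.name for p in out.glob("*.csv")),
        "truths": manifest["truths"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
    return run_manifest
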