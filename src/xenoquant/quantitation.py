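"""Concentration estimation with correction and censoring rules.

Unknown responses are inverse-predicted through the matrix-matched curve,
conditionally divided by the average extraction recovery (only when the
result is above the average LOQ or its S/N exceeds 10), reduced by the
system-blank contamination for flagged analytes, and assigned a censoring
status against LOD/LOQ.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CalibrationCurve, SensitivityEstimate, Status

log = logging.getLogger("xenoquant")


def invert_calibration(response: float, curve: CalibrationCurve) -> float:
    """Inverse prediction conc = (response - intercept)/slope, floored at 0."""
    if curve.slope == 0:
        raise ValueError("zero-slope curve")
    if not np.isfinite(response):
        raise ValueError("non-finite response")
    return max((response - curve.intercept) / curve.slope, 0.0)


def apply_recovery_rule(
    conc: float,
    avg_recovery: float,
    avg_loq: float,
    snr: Optional[float] = None,
) -> tuple[float, bool]:
    """Conditional recovery correction.

    The concentration is divided by the average extraction recovery only if
    it exceeds the average LOQ or the measurement's S/N exceeds 10 —
    trace-level signals near the noise are left uncorrected.
    """
    if avg_recovery <= 0:
        raise ValueError("average recovery must be positive")
    if avg_recovery > 1.2:
        raise ValueError("average recovery outside plausible range (> 120%)")
    eligible = conc > avg_loq or (snr is not None and snr > 10)
    if eligible:
        return conc / avg_recovery, True
    return conc, False


def censor(
    conc: float,
    lod: float,
    loq: float,
    snr: Optional[float] = None,
    range_max: Optional[float] = None,
) -> str:
    """Assign a censoring status.

    At or above the LOQ (or S/N > 10) the value is quantified; at or above
    the LOD but below the LOQ it is reported only as below the LOQ; below
    the LOD it is below the LOD. Values above the top calibrant are flagged
    instead of extrapolated.
    """
    if lod > loq:
        raise ValueError("LOD must not exceed LOQ")
    if range_max is not None and conc > range_max:
        return Status.above_range.value
    if conc >= loq or (snr is not None and snr > 10):
        return Status.quantified.value
    if conc >= lod:
        return Status.below_loq.value
    return Status.below_lod.value


def substitute_censored(value: float, status: str, loq: float, policy: str) -> float:
    """Replace a censored value under a named substitution policy.

    ``half_loq`` (descriptive statistics), ``at_loq`` (upper-bound intake)
    or ``zero``. Quantified values pass through unchanged.
    """
    if policy not in ("half_loq", "at_loq", "zero"):
        raise ValueError(f"unknown substitution policy {policy!r}")
    if status == Status.quantified.value:
        return value
    if status in (Status.below_loq.value, Status.below_lod.value, Status.not_detected.value):
        return {"half_loq": loq / 2.0, "at_loq": loq, "zero": 0.0}[policy]
    return value


def blank_contamination(
    system_blanks: pd.DataFrame, solvent_curve: CalibrationCurve
) -> float:
    """Mean system-blank concentration via the solvent calibration."""
    if len(system_blanks) < 3:
        raise ValueError(
            f"need >=3 system blanks for {solvent_curve.analyte}, got {len(system_blanks)}"
        )
    concs = [
        invert_calibration(a, solvent_curve)
        for a in system_blanks["response" if "response" in system_blanks else "area"]
    ]
    return float(np.mean(concs))


def blank_correct(
    results: pd.DataFrame,
    contamination: dict[str, float],
    flagged: set[str],
) -> pd.DataFrame:
    """Subtract system contamination from flagged analytes' concentrations.

    ``contamination`` maps analyte -> blank level (ng/mL, from
    :func:`blank_contamination`). Only analytes in ``flagged`` are
    corrected; corrected values are floored at 0 and ``blank_subtracted``
    records the amount removed. Unflagged analytes with contaminated blanks
    are left unchanged with a warning.
    """
    df = results.copy()
    if "blank_corrected" not in df:
        df["blank_corrected"] = False
    if "blank_subtracted" not in df:
        df["blank_subtracted"] = 0.0
    for analyte, level in contamination.items():
        mask = df["analyte"] == analyte
        if analyte not in flagged:
            if level > 0 and mask.any():
                log.warning(
                    "analyte %s has contaminated blanks (%.3g ng/mL) but is not "
                    "flagged for blank correction; leaving results unchanged",
                    analyte, level,
                )
            continue
        corrected = np.maximum(df.loc[mask, "conc"].astype(float) - level, 0.0)
        df.loc[mask, "blank_subtracted"] = (
            df.loc[mask, "conc"].astype(float) - corrected
        )
        df.loc[mask, "conc"] = corrected
        df.loc[mask, "blank_corrected"] = True
    return df


def quantify_unknowns(
    measurements: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    sensitivities: dict[str, SensitivityEstimate],
    recoveries: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Full quantitation of unknown-role measurements for one matrix.

    Applies inverse prediction, the conditional recovery rule and censoring.
    Blank correction is a separate pass (:func:`blank_correct`) because its
    input is the blank set, not the unknowns.
    """
    recoveries = recoveries or {}
    rows = []
    for rec in measurements.itertuples(index=False):
        curve = curves.get(rec.analyte)
        sens = sensitivities.get(rec.analyte)
        if curve is None or sens is None:
            log.warning("no calibration for %s; skipping", rec.analyte)
            continue
        response = getattr(rec, "response", rec.area)
        conc = invert_calibration(response, curve)
        noise = getattr(rec, "noise", None)
        snr = None
        if noise is not None and np.isfinite(noise) and noise > 0:
            snr = (response - curve.intercept) / noise
        corrected = False
        if rec.analyte in recoveries:
            conc, corrected = apply_recovery_rule(
                conc, recoveries[rec.analyte], sens.loq, snr
            )
        status = censor(conc, sens.lod, sens.loq, snr, curve.range_max)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "analyte": rec.analyte,
                "conc": conc,
                "status": status,
                "recovery_corrected": corrected,
                "blank_corrected": False,
                "blank_subtracted": 0.0,
                "snr": snr if snr is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def recensor(results: pd.DataFrame, sensitivities: dict[str, SensitivityEstimate]) -> pd.DataFrame:
    """Re-assign censoring statuses after blank correction.

    The raw S/N is not reused here: it includes the subtracted contamination
    signal, so statuses are reassigned on concentration alone.
    """
    df = results.copy()
    for i, rec in df.iterrows():
        sens = sensitivities.get(rec["analyte"])
        if sens is None:
            continue
        if rec["status"] != Status.above_range.value:
            df.at[i, "status"] = censor(rec["conc"], sens.lod, sens.loq, None)
    return df
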