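"""Weighted calibration fitting, matrix-effect and sensitivity estimation.

Calibration lines are fitted by 1/x-weighted least squares — the weighting
that matches the heteroscedastic (roughly proportional) noise of trace-level
MRM peak areas. The matrix effect (SSE) is the percent ratio of the
matrix-matched to the solvent slope; LOD/LOQ are the concentrations where
the signal-to-noise ratio reaches 3 and 10.
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import CalibrationCurve, SensitivityEstimate

log = logging.getLogger("xenoquant")

MIN_LEVELS = 5


def fit_calibration(
    points: Sequence[tuple[float, float]],
    weighting: str = "inverse_x",
    analyte: str = "",
    matrix: str = "",
    used_is: bool = False,
) -> CalibrationCurve:
    """Fit a weighted linear calibration ``response = a + b*conc``.

    Minimises sum w_i (y_i - a - b x_i)^2 with w_i = 1/x_i (or 1). Zero
    concentrations are excluded under 1/x weighting. Requires at least five
    distinct non-zero levels. R^2 is the weighted coefficient of
    determination, evaluated on the same objective that was minimised.
    """
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite calibration point")
    if weighting == "inverse_x":
        keep = x > 0
        if (~keep).any():
            log.warning("excluding %d zero-concentration point(s) under 1/x weighting",
                        int((~keep).sum()))
        x, y = x[keep], y[keep]
        w = 1.0 / x
    elif weighting == "none":
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if len(np.unique(x)) < MIN_LEVELS:
        raise ValueError(
            f"insufficient calibration levels for {analyte or '?'}: "
            f"{len(np.unique(x))} < {MIN_LEVELS}"
        )
    # closed-form weighted normal equations
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    ss_res = (w * resid**2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        analyte=analyte,
        matrix=matrix,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        weighting=weighting,
        range_min=float(x.min()),
        range_max=float(x.max()),
        used_is=used_is,
        n_points=int(len(x)),
    )


def normalize_by_is(
    measurements: pd.DataFrame, is_map: Mapping[str, str]
) -> pd.DataFrame:
    """Express analyte response as area / internal-standard area where mapped.

    Analytes absent from ``is_map`` keep their raw area as response. Mapped
    rows with a missing or non-positive IS area are dropped with a warning.
    Adds ``response`` and ``used_is`` columns.
    """
    df = measurements.copy()
    mapped = df["analyte"].isin(is_map.keys())
    df["used_is"] = mapped
    df["response"] = df["area"].astype(float)
    bad = mapped & (df["is_area"].isna() | (df["is_area"] <= 0))
    if bad.any():
        log.warning(
            "dropping %d measurement(s) with missing IS area: %s",
            int(bad.sum()),
            df.loc[bad, "sample_id"].tolist(),
        )
        df = df[~bad].copy()
        mapped = df["analyte"].isin(is_map.keys())
    df.loc[mapped, "response"] = (
        df.loc[mapped, "area"].astype(float) / df.loc[mapped, "is_area"].astype(float)
    )
    return df


def compute_sse(matrix_curve: CalibrationCurve, solvent_curve: CalibrationCurve) -> float:
    """Signal suppression/enhancement in percent (matrix slope / solvent slope).

    Values below 100% indicate ionisation suppression by the matrix, above
    100% enhancement.
    """
    if matrix_curve.analyte != solvent_curve.analyte:
        raise ValueError("SSE requires curves for the same analyte")
    if matrix_curve.weighting != solvent_curve.weighting or (
        matrix_curve.used_is != solvent_curve.used_is
    ):
        raise ValueError("SSE requires matching weighting and IS usage")
    if solvent_curve.slope <= 0:
        raise ValueError(f"unusable solvent calibration for {solvent_curve.analyte}")
    return 100.0 * matrix_curve.slope / solvent_curve.slope


def estimate_lod_loq(
    calibrants: pd.DataFrame,
    curve: Optional[CalibrationCurve] = None,
    analyte: str = "",
    matrix: str = "",
) -> SensitivityEstimate:
    """Estimate LOD (S/N = 3) and LOQ (S/N = 10) from calibrants with noise.

    Per-point S/N = (area - intercept) / noise; the intercept defaults to 0
    when no curve is supplied. The LOQ is the lowest calibrant whose S/N
    reaches 10 when lower levels bracket the threshold; otherwise the S/N
    trend is interpolated log-linearly to S/N = 10 (and extrapolated from
    the lowest levels when every point is above threshold). The LOD follows
    the same rule at S/N = 3.
    """
    df = calibrants.dropna(subset=["noise"])
    if len(df) == 0 or (df["noise"] <= 0).any():
        raise ValueError("S/N undefined: per-point noise required and must be positive")
    intercept = curve.intercept if curve is not None else 0.0
    grp = df.groupby("nominal_conc").agg(area=("area", "mean"), noise=("noise", "mean"))
    grp = grp.sort_index()
    conc = grp.index.to_numpy(dtype=float)
    snr = (grp["area"].to_numpy() - intercept) / grp["noise"].to_numpy()
    usable = snr > 0
    conc, snr = conc[usable], snr[usable]
    if len(conc) == 0 or snr.max() < 3:
        raise ValueError(f"analyte {analyte or '?'} not detectable in this design")

    def threshold_conc(target: float) -> tuple[float, str]:
        above = snr >= target
        if len(conc) < 2:
            return float(conc[0]), "lowest-level"
        if above.any():
            idx = int(np.argmax(above))
            if idx > 0:
                # bracketing pair: log-linear interpolation between the two
                # levels straddling the threshold (exact for S/N linear in
                # concentration, insensitive to the level grid spacing)
                c0, c1 = conc[idx - 1], conc[idx]
                s0, s1 = snr[idx - 1], snr[idx]
                if s1 == s0:
                    return float(c1), "lowest-level"
                t = (np.log(target) - np.log(s0)) / (np.log(s1) - np.log(s0))
                return float(np.exp(np.log(c0) + t * (np.log(c1) - np.log(c0)))), "interpolated"
        # threshold outside the level range: extrapolate a global log-linear fit
        b, a = np.polyfit(np.log(conc), np.log(snr), 1)
        if b <= 0:
            # S/N not increasing with concentration: fall back to a level
            idx = int(np.argmax(above)) if above.any() else len(conc) - 1
            return float(conc[idx]), "lowest-level"
        return float(np.exp((np.log(target) - a) / b)), "interpolated"

    loq, method_q = threshold_conc(10.0)
    lod, method_d = threshold_conc(3.0)
    lod = min(lod, loq)
    method = "interpolated" if "interpolated" in (method_q, method_d) else "lowest-level"
    return SensitivityEstimate(
        analyte=analyte or (curve.analyte if curve else ""),
        matrix=matrix or (curve.matrix if curve else ""),
        lod=lod,
        loq=loq,
        method=method,
    )


def average_sensitivity(estimates: Sequence[SensitivityEstimate]) -> SensitivityEstimate:
    """Arithmetic mean of per-run LOD/LOQ estimates ("average LOQ")."""
    if not estimates:
        raise ValueError("no sensitivity estimates to average")
    return SensitivityEstimate(
        analyte=estimates[0].analyte,
        matrix=estimates[0].matrix,
        lod=float(np.mean([e.lod for e in estimates])),
        loq=float(np.mean([e.loq for e in estimates])),
        method=estimates[0].method,
    )
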