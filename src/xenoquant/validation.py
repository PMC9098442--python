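"""Guideline-style in-house method validation.

Per analyte/matrix and spiking level (3x and 30x the approximate LOQ, in
triplicate over three days), computes extraction recovery, intermediate
precision (RSD across all nine spike results), repeatability (RSD of six
same-day injections), weighted-fit linearity and selectivity, and evaluates
each against the method's acceptance limits: recovery 50-120%, precision
below a concentration-tiered RSD ceiling stricter than the Horwitz
tolerance, R^2 > 0.9, and blank interference below a configurable fraction
of the lowest calibrant.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

RECOVERY_WINDOW = (50.0, 120.0)
R2_LIMIT = 0.9
SELECTIVITY_FRACTION = 0.30  # blank response tolerated, as fraction of lowest calibrant

CRITERIA = ("recovery", "intermediate_precision", "repeatability", "linearity", "selectivity")


def recovery(measured_conc: float, spiked_conc: float) -> float:
    """Extraction recovery: detected / spiked concentration, in percent."""
    if spiked_conc <= 0:
        raise ValueError("spiked concentration must be positive")
    return 100.0 * measured_conc / spiked_conc


def precision_rsd(values: Sequence[float]) -> float:
    """Relative standard deviation (sample sd, n-1) in percent of the mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("precision needs at least two values")
    m = v.mean()
    if m == 0:
        raise ValueError("mean of zero: RSD undefined")
    return 100.0 * v.std(ddof=1) / abs(m)


def horwitz_rsd(conc_ng_ml: float) -> float:
    """Horwitz minimum intermediate-precision tolerance in percent.

    RSD% = 2^(1 - 0.5 log10 C) with C the dimensionless mass fraction;
    ng/mL converts as C = conc * 1e-9 (aqueous density convention).
    """
    if conc_ng_ml <= 0:
        raise ValueError("concentration must be positive")
    c = conc_ng_ml * 1e-9
    return 2.0 ** (1.0 - 0.5 * math.log10(c))


def custom_precision_limit(conc_ng_ml: float) -> float:
    """Tiered RSD ceiling (%) stricter than Horwitz at trace levels."""
    if conc_ng_ml <= 0:
        raise ValueError("concentration must be positive")
    if conc_ng_ml < 10:
        return 32.0
    if conc_ng_ml < 100:
        return 27.0
    if conc_ng_ml < 1000:
        return 23.0
    return 16.0


def check_selectivity(
    matrix_blank_responses: Sequence[float],
    system_blank_responses: Sequence[float],
    lowest_calibrant_response: float,
    fraction: float = SELECTIVITY_FRACTION,
) -> bool:
    """Selectivity passes when mean blank response stays below
    ``fraction`` of the lowest calibrant's response (both blank kinds)."""
    if len(matrix_blank_responses) < 3 or len(system_blank_responses) < 3:
        raise ValueError("selectivity requires triplicate matrix and system blanks")
    threshold = fraction * lowest_calibrant_response
    return (
        float(np.mean(matrix_blank_responses)) <= threshold
        and float(np.mean(system_blank_responses)) <= threshold
    )


def evaluate_analyte(record: dict) -> tuple[dict, bool]:
    """Evaluate one analyte/matrix/level record against all criteria.

    ``record`` carries recovery_pct, intermediate_precision_rsd,
    repeatability_rsd, r2, selectivity_ok and level_conc (the nominal spike
    concentration that selects the precision tier). Metrics that are absent
    are marked "not evaluable" and fail the conjunction.
    """
    verdicts: dict[str, str] = {}
    level_conc = record.get("level_conc")

    def verdict(name: str, value, ok) -> None:
        if value is None or (isinstance(value, float) and not math.isfinite(value)):
            verdicts[name] = "not evaluable"
        else:
            verdicts[name] = "pass" if ok(value) else "fail"

    verdict("recovery", record.get("recovery_pct"),
            lambda r: RECOVERY_WINDOW[0] <= r <= RECOVERY_WINDOW[1])
    limit = custom_precision_limit(level_conc) if level_conc else None
    verdict("intermediate_precision", record.get("intermediate_precision_rsd"),
            lambda r: limit is not None and r <= limit)
    verdict("repeatability", record.get("repeatability_rsd"),
            lambda r: limit is not None and r <= limit)
    verdict("linearity", record.get("r2"), lambda r: r > R2_LIMIT)
    sel = record.get("selectivity_ok")
    verdicts["selectivity"] = (
        "not evaluable" if sel is None else ("pass" if sel else "fail")
    )
    fulfils_all = all(v == "pass" for v in verdicts.values())
    return verdicts, fulfils_all


def validate_spikes(
    spikes: pd.DataFrame,
    repeat_injections: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Compute per-analyte/level validation metrics from quantified spikes.

    ``spikes`` needs columns analyte, nominal_conc, day, conc (the measured
    concentration before recovery correction); the nine results per level
    (3 days x 3 replicates) give the mean recovery and the intermediate
    precision. ``repeat_injections`` (six same-day measurements per
    analyte/level) gives the repeatability.
    """
    rows = []
    for (analyte, level), grp in spikes.groupby(["analyte", "nominal_conc"]):
        rec = [recovery(c, level) for c in grp["conc"]]
        row = {
            "analyte": analyte,
            "level_conc": float(level),
            "n": len(grp),
            "recovery_pct": float(np.mean(rec)),
            "intermediate_precision_rsd": precision_rsd(grp["conc"]) if len(grp) >= 2 else np.nan,
        }
        if repeat_injections is not None:
            rep = repeat_injections[
                (repeat_injections["analyte"] == analyte)
                & (repeat_injections["nominal_conc"] == level)
            ]
            row["repeatability_rsd"] = (
                precision_rsd(rep["conc"]) if len(rep) >= 2 else np.nan
            )
        else:
            row["repeatability_rsd"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_matrix(records: pd.DataFrame) -> dict:
    """Matrix-level validation summary.

    Fraction of analytes fulfilling every criterion at at least one spiking
    level, and the median recovery over all records.
    """
    per_analyte = records.groupby("analyte")["fulfils_all"].any()
    return {
        "n_analytes": int(per_analyte.size),
        "pct_fulfilling": 100.0 * float(per_analyte.mean()),
        "median_recovery": float(records["recovery_pct"].median()),
    }
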