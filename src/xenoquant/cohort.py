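"""Descriptive cohort statistics with censoring awareness.

Detection summaries (positive counts with "<LOQ" extremes), half-LOQ
substituted distribution quartiles, pairwise inter-analyte correlation of
longitudinal series, covariate normalisation and paired treated/untreated
comparisons.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantitation import substitute_censored
from .types import PairedComparison, Status

DETECTED_STATUSES = {Status.quantified.value, Status.below_loq.value}


def detection_summary(results: pd.DataFrame, cohort: str = "") -> Optional[dict]:
    """Table-1-style summary for one analyte in one cohort.

    Counts detections (quantified or below-LOQ), reports min/max over
    quantified values with the "<LOQ" token when the extreme observation
    was censored. Returns None when nothing was detected (row suppressed).
    """
    if len(results) == 0:
        raise ValueError("empty cohort")
    detected = results[results["status"].isin(DETECTED_STATUSES)]
    if len(detected) == 0:
        return None
    quantified = detected[detected["status"] == Status.quantified.value]
    any_censored = (detected["status"] == Status.below_loq.value).any()
    if len(quantified) > 0:
        min_tok = "<LOQ" if any_censored else f"{quantified['conc'].min():.3g}"
        max_tok = f"{quantified['conc'].max():.3g}"
    else:
        min_tok = max_tok = "<LOQ"
    return {
        "analyte": results["analyte"].iloc[0] if "analyte" in results else "",
        "cohort": cohort,
        "n_positive": int(len(detected)),
        "min_conc": min_tok,
        "max_conc": max_tok,
    }


def distribution_summary(
    results: pd.DataFrame, loq: float, policy: str = "half_loq"
) -> tuple[float, float, float]:
    """Quartiles (Q1, median, Q3) with censored values substituted.

    Uses linear interpolation between order statistics, the same convention
    as the violin-plot summaries.
    """
    detected = results[results["status"].isin(DETECTED_STATUSES)]
    if len(detected) == 0:
        raise ValueError("no detections")
    values = [
        substitute_censored(row["conc"], row["status"], loq, policy)
        for _, row in detected.iterrows()
    ]
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


def correlation_matrix(
    table: pd.DataFrame,
    method: str = "spearman",
    policy: str = "half_loq",
    min_overlap: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation of longitudinal per-day series.

    ``table`` is long-format with analyte, day, conc, censored and
    reporting_limit columns. Censored days enter at the substituted value;
    correlation is computed over days where both analytes were sampled.
    Returns (correlation matrix, n-overlap matrix); cells with fewer than
    ``min_overlap`` common days, or a constant series, are NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    df = table.copy()
    df["value"] = np.where(
        df["censored"], df["reporting_limit"] / 2.0 if policy == "half_loq" else 0.0,
        df["conc"],
    )
    wide = df.pivot_table(index="day", columns="analyte", values="value", aggfunc="mean")
    analytes = list(wide.columns)
    corr = pd.DataFrame(np.nan, index=analytes, columns=analytes)
    nmat = pd.DataFrame(0, index=analytes, columns=analytes)
    for i, a in enumerate(analytes):
        for b in analytes[i:]:
            if a == b:
                n = int(wide[a].notna().sum())
                nmat.loc[a, a] = n
                if n >= min_overlap:
                    corr.loc[a, a] = 1.0
                continue
            pair = wide[[a, b]].dropna()
            nmat.loc[a, b] = nmat.loc[b, a] = len(pair)
            if len(pair) < min_overlap:
                continue
            if pair[a].nunique() == 1 or pair[b].nunique() == 1:
                continue  # constant series: correlation undefined, not 0
            if method == "spearman":
                r = stats.spearmanr(pair[a], pair[b]).statistic
            else:
                r = stats.pearsonr(pair[a], pair[b]).statistic
            corr.loc[a, b] = corr.loc[b, a] = float(r)
    return corr, nmat


def paired_compare(
    untreated: pd.DataFrame, treated: pd.DataFrame, analyte: str = ""
) -> PairedComparison:
    """Median treated/untreated concentration ratio over matched samples.

    Pairs are matched on sample_id; pairs where either member is censored
    or the untreated concentration is zero are excluded and counted.
    """
    merged = untreated.merge(
        treated, on="sample_id", suffixes=("_untreated", "_treated")
    )
    if len(merged) == 0:
        raise ValueError("no matched sample pairs")
    ok = (
        (merged["status_untreated"] == Status.quantified.value)
        & (merged["status_treated"] == Status.quantified.value)
        & (merged["conc_untreated"] > 0)
    )
    excluded = int((~ok).sum())
    valid = merged[ok]
    if len(valid) == 0:
        raise ValueError("all pairs lost to censoring")
    ratios = valid["conc_treated"] / valid["conc_untreated"]
    return PairedComparison(
        analyte=analyte or str(merged.get("analyte_untreated", pd.Series([""])).iloc[0]),
        n_pairs=int(len(valid)),
        median_ratio=float(ratios.median()),
        n_excluded=excluded,
        note=f"{excluded} pair(s) excluded (censoring or zero denominator)",
    )


def normalize_to_covariate(conc: float, covariate: float) -> float:
    """Concentration per unit covariate (e.g. ng per mg creatinine)."""
    if covariate <= 0:
        raise ValueError("covariate must be positive")
    return conc / covariate
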