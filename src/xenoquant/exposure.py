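"""Infant exposure and risk assessment from breast-milk concentrations.

Implements the high-exposure scenario: each analyte is assigned an assumed
milk concentration (the maximum quantified level, or the LOQ when only seen
below it), converted to a hypothetical upper-bound intake

    hUBI [ug/kg bw/day] = conc [ng/mL] * 1000 mL/day / (6 kg * 1000 ng/ug)

and compared against health-based guidance. TDI/ADI values are corrected by
one-third for infants under 16 weeks and reported as the ratio
guidance/hUBI; BMDL10 values (genotoxic carcinogens) are compared
uncorrected as a margin of exposure, with MoE < 10,000 flagged as a
potential concern.

Two ratio conventions are emitted side by side: ``ratio``/``moe`` divide
full-precision intermediates, while the ``_compat`` variants divide the
display-rounded (2 s.f.) values, matching how a report computed from its own
printed cells would read.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .display import display_ratio, display_value, round_sig
from .io import builtin_panel_path
from .types import ExposureAssessment, Status

#: default consumption scenario
INTAKE_VOLUME_ML = 1000.0
BODY_WEIGHT_KG = 6.0
#: EFSA correction factor for infants below 16 weeks
INFANT_FACTOR = 3.0
#: margin-of-exposure threshold of low concern for genotoxic carcinogens
MOE_THRESHOLD = 10_000.0


def assumed_concentration(
    results: pd.DataFrame, loq: float
) -> tuple[float, str]:
    """Assumed milk concentration under the high-exposure scenario.

    ``results`` is a quantitation table slice for one analyte with ``conc``
    and ``status`` columns. Returns the maximum quantified concentration, or
    the LOQ when every detection was below it, with its provenance.
    """
    if len(results) == 0:
        raise ValueError("empty result series")
    detected = results[results["status"].isin(
        [Status.quantified.value, Status.below_loq.value]
    )]
    if len(detected) == 0:
        raise ValueError("no detections; analyte excluded from assessment")
    quantified = detected[detected["status"] == Status.quantified.value]
    if len(quantified) > 0:
        return float(quantified["conc"].max()), "max_quantified"
    return float(loq), "loq"


def hubi(
    conc: float,
    intake_volume: float = INTAKE_VOLUME_ML,
    bw: float = BODY_WEIGHT_KG,
) -> float:
    """Hypothetical upper-bound intake in ug/kg bw/day from conc in ng/mL."""
    if bw <= 0:
        raise ValueError("body weight must be positive")
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    return conc * intake_volume / bw / 1000.0


def infant_guidance(adult_value: float, factor: float = INFANT_FACTOR) -> float:
    """Infant-corrected TDI/ADI: one-third of the adult value."""
    if adult_value <= 0:
        raise ValueError("guidance value must be positive")
    return adult_value / factor


def risk_ratio(guidance_infant: float, hubi_value: float) -> float:
    """Guidance-to-intake ratio (full precision; display separately)."""
    if hubi_value <= 0:
        raise ValueError("hUBI must be positive for a finite ratio")
    return guidance_infant / hubi_value


def moe(bmdl10: float, hubi_value: float) -> tuple[float, bool]:
    """Margin of exposure BMDL10/hUBI and its concern flag (MoE < 10,000)."""
    if hubi_value <= 0 or bmdl10 <= 0:
        raise ValueError("MoE requires positive BMDL10 and hUBI")
    m = bmdl10 / hubi_value
    return m, m < MOE_THRESHOLD


def compat_ratio(numerator: float, hubi_value: float) -> float:
    """Ratio computed from display-rounded operands (report arithmetic)."""
    return display_ratio(display_value(numerator) / display_value(hubi_value))


def cumulative_hubi(
    concs: Iterable[float],
    intake_volume: float = INTAKE_VOLUME_ML,
    bw: float = BODY_WEIGHT_KG,
) -> float:
    """Class-cumulative hUBI: sum of assumed concentrations as one intake."""
    concs = list(concs)
    if not concs:
        raise ValueError("empty group")
    return hubi(sum(concs), intake_volume, bw)


def assess_one(
    name: str,
    assumed_conc: float,
    assumed_from: str,
    guidance: Optional[dict] = None,
    chemical_class: str = "",
) -> ExposureAssessment:
    """Build one assessment row from an assumed concentration and guidance."""
    h = hubi(assumed_conc)
    row = ExposureAssessment(
        analyte=name,
        chemical_class=chemical_class,
        assumed_conc=assumed_conc,
        assumed_from=assumed_from,
        hubi=h,
    )
    if guidance:
        kind, value = guidance["kind"], float(guidance["value"])
        row.guidance_kind = kind
        row.guidance_adult = value
        if kind == "BMDL10":
            m, concern = moe(value, h)
            row.moe = m
            row.moe_compat = compat_ratio(value, h)
            row.concern = concern
        else:
            gi = infant_guidance(value)
            row.guidance_infant = gi
            row.ratio = risk_ratio(gi, h)
            row.ratio_compat = compat_ratio(gi, h)
    return row


def load_assessment_inputs(path=None) -> list[dict]:
    """Load the exposure registry (assumed concentrations + guidance)."""
    with open(path or builtin_panel_path()) as fh:
        raw = yaml.safe_load(fh)
    return raw["analytes"]


def build_assessment_table(
    entries: Optional[Sequence[dict]] = None,
    quant_by_analyte: Optional[dict] = None,
    panel: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Assemble the risk-assessment table.

    Either pass ``entries`` (registry dicts with ``assumed_conc`` already
    chosen, as shipped in the built-in config) or ``quant_by_analyte``
    mapping analyte name to ``(quant results DataFrame, loq)`` with a
    ``panel`` of AnalyteSpec supplying class and guidance. Analytes with no
    detections are excluded. Rows are ordered by class then name.
    """
    rows: list[ExposureAssessment] = []
    if entries is not None:
        for e in entries:
            rows.append(
                assess_one(
                    e["name"],
                    float(e["assumed_conc"]),
                    e.get("assumed_from", "max_quantified"),
                    e.get("guidance"),
                    e.get("chemical_class", ""),
                )
            )
    else:
        if quant_by_analyte is None or panel is None:
            raise ValueError("need either entries or (quant_by_analyte, panel)")
        by_name = {s.name: s for s in panel}
        for name, (res, loq) in quant_by_analyte.items():
            try:
                conc, origin = assumed_concentration(res, loq)
            except ValueError:
                continue  # no detections -> excluded
            spec = by_name.get(name)
            guidance = (
                spec.guidance.model_dump() if spec is not None and spec.guidance else None
            )
            rows.append(
                assess_one(
                    name, conc, origin, guidance,
                    spec.chemical_class if spec is not None else "",
                )
            )
    records = []
    for r in sorted(rows, key=lambda r: (r.chemical_class, r.analyte)):
        rec = r.model_dump()
        rec["hubi_display"] = display_value(r.hubi)
        rec["guidance_infant_display"] = (
            display_value(r.guidance_infant) if r.guidance_infant is not None else None
        )
        rec["ratio_display"] = display_ratio(r.ratio) if r.ratio is not None else None
        rec["moe_display"] = display_ratio(r.moe) if r.moe is not None else None
        records.append(rec)
    return pd.DataFrame(records)


def class_cumulative_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-class cumulative hUBI from an assessment table."""
    out = (
        df.groupby("chemical_class")["assumed_conc"]
        .sum()
        .map(hubi)
        .rename("cumulative_hubi")
        .reset_index()
    )
    out["cumulative_hubi_display"] = out["cumulative_hubi"].map(lambda v: round_sig(v, 1))
    return out
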