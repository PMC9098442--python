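"""Synthetic instrument and cohort data with known ground truth.

Emulates the wet-lab and instrument stages of a targeted MRM study well
enough to exercise every downstream estimator: matrix-matched and solvent
calibration series spanning two decades around the true LOQ, triplicate
spiking experiments at 3x and 30x the LOQ across three days, triplicate
water blanks carrying system contamination, and unknown cohorts.

Signal model for a prepared concentration c measured in matrix m:

    mu   = slope_m * (c * recovery + c_blank) + intercept
    area = max(mu * (1 + cv * e1) + floor * e2, 0),   e1, e2 ~ N(0, 1)

where slope_m = solvent slope x SSE for matrix signals. The noise floor is
emitted as an explicit per-measurement ``noise`` column, so S/N =
(area - intercept)/floor and the true LOQ (S/N = 10) is 10*floor/slope_m in
closed form. Contamination is modelled as a fixed post-extraction
concentration present in every extract, including the water blanks — which
is what makes blank subtraction before recovery correction exact.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import AnalyteSpec, ExposureProfile, PEAK_COLUMNS, TruthRecord

log = logging.getLogger("xenoquant")

DEFAULT_DESIGN = {
    "cal_levels": 7,
    "spike_factors": (3.0, 30.0),  # x LOQ
    "replicates": 3,
    "days": 3,
    "blanks": 3,
    "unknowns": 0,
    "repeat_injections": 6,
    "day_effect_sd": 0.0,  # log-scale day-to-day instrument drift
    "is_base_area": 1000.0,
}


def _areas(rng: np.random.Generator, mu: np.ndarray, cv: float, floor: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    out = mu * (1.0 + cv * rng.standard_normal(mu.shape)) + floor * rng.standard_normal(mu.shape)
    return np.maximum(out, 0.0)


def generate_batch(
    panel: Sequence[AnalyteSpec],
    truths: Sequence[TruthRecord],
    design: Optional[dict] = None,
    seed: int = 0,
    unknown_concs: Optional[dict] = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a full validation-style measurement batch.

    Returns the peak table and a truth manifest (per-analyte TruthRecord
    dumps plus the design and seed). ``unknown_concs`` optionally fixes the
    true concentration of each unknown sample per analyte
    ({analyte: [conc, ...]}); otherwise unknowns are drawn log-normally
    around 10x the true LOQ.
    """
    design = {**DEFAULT_DESIGN, **(design or {})}
    if design["cal_levels"] < 5:
        raise ValueError("cal_levels must be >= 5")
    truth_by_name = {t.analyte: t for t in truths}
    missing = [s.name for s in panel if s.name not in truth_by_name]
    if missing:
        raise ValueError(f"panel analytes without truth records: {missing}")
    rng = np.random.default_rng(seed)
    day_factors = np.exp(design["day_effect_sd"] * rng.standard_normal(design["days"]))
    rows: list[dict] = []

    def emit(sample_id, spec, role, matrix, mu, truth, nominal=np.nan, day=np.nan,
             day_factor=1.0):
        area = float(_areas(rng, np.array([mu * day_factor]), truth.noise_cv,
                            truth.noise_floor)[0])
        is_area = np.nan
        if spec.internal_standard:
            is_area = float(
                _areas(rng, np.array([design["is_base_area"] * day_factor]),
                       truth.noise_cv, 0.0)[0]
            )
        rows.append({
            "sample_id": sample_id, "analyte": spec.name, "matrix": matrix,
            "role": role, "area": area, "qualifier_area": 0.4 * area,
            "noise": truth.noise_floor if truth.noise_floor > 0 else np.nan,
            "is_area": is_area, "nominal_conc": nominal, "day": day, "batch": "b1",
        })

    for spec in panel:
        t = truth_by_name[spec.name]
        # calibration levels: 2 decades centred on the (noise-free) LOQ scale
        if t.noise_floor > 0:
            lo = t.loq_true / 3.0
        else:
            lo = 0.01
        levels = lo * np.logspace(0, 2.3, design["cal_levels"])
        for i, c in enumerate(levels):
            emit(f"cal_{spec.name}_{i}", spec, "calibrant", spec.calibration_matrix,
                 t.matrix_slope * c + t.true_intercept, t, nominal=c)
            emit(f"scal_{spec.name}_{i}", spec, "solvent_calibrant", "solvent",
                 t.true_slope * c + t.true_intercept, t, nominal=c)
        # spikes: 3 days x replicates at each level; spikes pass through recovery
        # and carry the system contamination like any prepared extract
        for f in design["spike_factors"]:
            c = f * (t.loq_true if t.noise_floor > 0 else 10 * lo)
            if t.noise_floor > 0 and t.matrix_slope * c < t.noise_floor:
                log.warning("spike for %s indistinguishable from noise", spec.name)
            for d in range(design["days"]):
                for r in range(design["replicates"]):
                    emit(f"spk_{spec.name}_{f:g}_{d}_{r}", spec, "spike",
                         spec.calibration_matrix,
                         t.matrix_slope * (c * t.recovery_true + t.contamination_conc)
                         + t.true_intercept,
                         t, nominal=c, day=d, day_factor=day_factors[d])
        # repeatability: one validation batch (both levels) re-injected six times
        for f in design["spike_factors"]:
            c_rep = f * (t.loq_true if t.noise_floor > 0 else 10 * lo)
            for r in range(design["repeat_injections"]):
                emit(f"rep_{spec.name}_{f:g}_{r}", spec, "spike",
                     spec.calibration_matrix,
                     t.matrix_slope * (c_rep * t.recovery_true + t.contamination_conc)
                     + t.true_intercept,
                     t, nominal=c_rep, day=0, day_factor=day_factors[0])
                rows[-1]["batch"] = "rep"
        # triplicate water blanks (system) and matrix blanks
        for b in range(design["blanks"]):
            emit(f"sysblk_{spec.name}_{b}", spec, "system_blank", "water",
                 t.true_slope * t.contamination_conc + t.true_intercept, t)
            emit(f"matblk_{spec.name}_{b}", spec, "matrix_blank",
                 spec.calibration_matrix,
                 t.matrix_slope * t.contamination_conc + t.true_intercept, t)
        # unknowns
        concs = (unknown_concs or {}).get(spec.name)
        n_unknown = len(concs) if concs is not None else design["unknowns"]
        for u in range(n_unknown):
            c = (concs[u] if concs is not None
                 else float(np.exp(rng.normal(np.log(10 * lo), 1.0))))
            emit(f"unk_{u}_{spec.name}", spec, "unknown", spec.calibration_matrix,
                 t.matrix_slope * (c * t.recovery_true + t.contamination_conc)
                 + t.true_intercept,
                 t, day=np.nan)
            rows[-1]["true_conc"] = c
    df = pd.DataFrame(rows)
    for col in PEAK_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    manifest = {
        "seed": int(seed),
        "design": {k: (list(v) if isinstance(v, tuple) else v) for k, v in design.items()},
        "truths": {t.analyte: t.model_dump() for t in truths},
    }
    return df, manifest


def demo_inputs() -> tuple[list[AnalyteSpec], list[TruthRecord], list[ExposureProfile]]:
    """A small milk-matrix demo panel with realistic truths.

    Slopes, matrix effects and recoveries span the ranges seen in practice
    (recoveries centred low, as milk extraction loses polar analytes; LOQs
    in the 0.001-0.1 ng/mL decade); BPA-like members carry system
    contamination and the blank-correction flag.
    """
    specs = [
        AnalyteSpec(name="Bisphenol A (BPA)", chemical_class="plasticizer",
                    calibration_matrix="milk", blank_correct=True,
                    guidance={"kind": "TDI", "value": 4.0, "source": "EFSA"}),
        AnalyteSpec(name="Mono-n-butyl phthalate (MBP)", chemical_class="plasticizer",
                    calibration_matrix="milk", blank_correct=True),
        AnalyteSpec(name="Perfluorooctanoic acid (PFOA)", chemical_class="PFAS",
                    calibration_matrix="milk",
                    guidance={"kind": "TDI", "value": 0.63, "source": "EFSA"}),
        AnalyteSpec(name="Daidzein", chemical_class="phytoestrogen",
                    calibration_matrix="milk"),
        AnalyteSpec(name="Methylparaben (MP)", chemical_class="personal-care",
                    calibration_matrix="milk", internal_standard="MP-13C6",
                    guidance={"kind": "ADI", "value": 10000, "source": "EFSA"}),
        AnalyteSpec(name="Jacobine-N-oxide", chemical_class="phytotoxin",
                    calibration_matrix="milk",
                    guidance={"kind": "BMDL10", "value": 70, "source": "EFSA"}),
        AnalyteSpec(name="PhIP", chemical_class="food-processing",
                    calibration_matrix="milk",
                    guidance={"kind": "BMDL10", "value": 480, "source": "literature"}),
        AnalyteSpec(name="2-naphthol", chemical_class="industrial",
                    calibration_matrix="milk"),
    ]
    truth_params = {
        "Bisphenol A (BPA)": dict(true_slope=800, sse_true=0.8, recovery_true=0.60,
                                  noise_floor=1.3, contamination_conc=0.30),
        "Mono-n-butyl phthalate (MBP)": dict(true_slope=500, sse_true=0.7,
                                             recovery_true=0.54, noise_floor=1.0,
                                             contamination_conc=0.10),
        "Perfluorooctanoic acid (PFOA)": dict(true_slope=2000, sse_true=0.9,
                                              recovery_true=0.85, noise_floor=0.9),
        "Daidzein": dict(true_slope=3000, sse_true=1.1, recovery_true=0.75,
                         noise_floor=0.6),
        "Methylparaben (MP)": dict(true_slope=1500, sse_true=0.95, recovery_true=0.90,
                                   noise_floor=1.1),
        "Jacobine-N-oxide": dict(true_slope=5000, sse_true=0.85, recovery_true=0.65,
                                 noise_floor=0.8),
        "PhIP": dict(true_slope=10000, sse_true=1.05, recovery_true=0.80,
                     noise_floor=1.5),
        "2-naphthol": dict(true_slope=900, sse_true=0.75, recovery_true=0.70,
                           noise_floor=1.2),
    }
    truths = [
        TruthRecord(analyte=name, matrix="milk", noise_cv=0.05, **p)
        for name, p in truth_params.items()
    ]
    profiles = [
        ExposureProfile(analyte="Methylparaben (MP)", dynamics="episodic",
                        median_conc=0.5, dispersion=0.6, detection_prob=1.0,
                        correlation_group="parabens", reporting_limit=0.05),
        ExposureProfile(analyte="Daidzein", dynamics="constant", median_conc=0.02,
                        dispersion=1.0, detection_prob=0.6, reporting_limit=0.008),
        ExposureProfile(analyte="Perfluorooctanoic acid (PFOA)",
                        dynamics="accumulating", median_conc=0.05, dispersion=0.4,
                        detection_prob=0.9, reporting_limit=0.016),
        ExposureProfile(analyte="2-naphthol", dynamics="constant", median_conc=0.4,
                        dispersion=0.3, detection_prob=1.0, reporting_limit=0.1),
    ]
    return specs, truths, profiles


def generate_longitudinal(
    profiles: Sequence[ExposureProfile],
    n_days: int,
    sampling_gaps: bool = False,
    seed: int = 0,
    keep_prob: float = 0.6,
) -> pd.DataFrame:
    """Per-day concentration series with censor flags.

    Constant profiles fluctuate log-normally around the median; episodic
    profiles overlay rare large bursts (isolated exposure events); an
    accumulating profile hovers near its floor with a quarter of the stated
    dispersion (bioaccumulative compounds change slowly). Analytes sharing a
    ``correlation_group`` load on a common latent day factor (loading 0.9).
    Days are irregularly thinned when ``sampling_gaps`` is true. Values
    below the per-analyte reporting limit, and days where the compound
    evades detection, are emitted as censored.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    groups = sorted({p.correlation_group for p in profiles if p.correlation_group})
    factors = {g: rng.standard_normal(n_days) for g in groups}
    loading = 0.9
    if sampling_gaps:
        kept = np.flatnonzero(rng.random(n_days) < keep_prob)
        if kept.size == 0:
            kept = np.array([0])
    else:
        kept = np.arange(n_days)
    rows = []
    for p in profiles:
        eps = rng.standard_normal(n_days)
        if p.correlation_group:
            z = loading * factors[p.correlation_group] + np.sqrt(1 - loading**2) * eps
        else:
            z = eps
        disp = p.dispersion * (0.25 if p.dynamics == "accumulating" else 1.0)
        conc = p.median_conc * np.exp(disp * z)
        if p.dynamics == "episodic":
            burst = rng.random(n_days) < 0.1
            conc = conc * np.where(burst, np.exp(rng.normal(np.log(10), 0.5, n_days)), 1.0)
        detected = rng.random(n_days) < p.detection_prob
        for d in kept:
            censored = (not detected[d]) or conc[d] < p.reporting_limit
            rows.append({
                "analyte": p.analyte,
                "day": int(d),
                "conc": np.nan if censored else float(conc[d]),
                "censored": bool(censored),
                "reporting_limit": p.reporting_limit,
            })
    return pd.DataFrame(rows)
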