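"""Domain types for the targeted MRM quantitation pipeline.

Panel and configuration entries are validated pydantic models; bulk tabular
data (peak measurements, quantitation results) lives in pandas DataFrames
whose schemas are declared here and enforced by :mod:`xenoquant.io`.
"""
from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

CHEMICAL_CLASSES = (
    "plasticizer",
    "PFAS",
    "industrial",
    "phytoestrogen",
    "mycoestrogen",
    "personal-care",
    "phytotoxin",
    "food-processing",
    "air-pollutant",
)

MATRICES = ("urine", "serum", "plasma", "milk", "water", "solvent")


class Role(str, enum.Enum):
    """Role of a peak measurement in the experimental design."""

    calibrant = "calibrant"
    solvent_calibrant = "solvent_calibrant"
    spike = "spike"
    matrix_blank = "matrix_blank"
    system_blank = "system_blank"
    unknown = "unknown"


class Status(str, enum.Enum):
    """Censoring status of a quantitation result."""

    quantified = "quantified"
    below_loq = "below_loq"
    below_lod = "below_lod"
    above_range = "above_range"
    not_detected = "not_detected"


#: roles that require a nominal (spiked/prepared) concentration
ROLES_WITH_NOMINAL = {Role.calibrant.value, Role.solvent_calibrant.value, Role.spike.value}

#: column order of a peak-measurement table
PEAK_COLUMNS = [
    "sample_id",
    "analyte",
    "matrix",
    "role",
    "area",
    "qualifier_area",
    "noise",
    "is_area",
    "nominal_conc",
    "day",
    "batch",
]

#: column order of a quantitation-result table
QUANT_COLUMNS = [
    "sample_id",
    "analyte",
    "conc",
    "status",
    "recovery_corrected",
    "blank_corrected",
    "blank_subtracted",
    "snr",
]


class GuidanceValue(BaseModel):
    """Health-based guidance value in ug per kg body weight per day.

    ``kind`` determines the downstream risk metric: TDI/ADI values are
    corrected for infants and compared as a ratio, BMDL10 values enter a
    margin-of-exposure calculation uncorrected.
    """

    kind: str = Field(pattern="^(TDI|ADI|BMDL10)$")
    value: float = Field(gt=0)
    source: str = ""


class AnalyteSpec(BaseModel):
    """One analyte panel entry.

    ``calibration_matrix`` is the single matrix whose matrix-matched
    calibration quantifies this analyte (the most sensitive matrix);
    ``blank_correct`` marks the contamination-prone compounds whose results
    are corrected by the system-blank level.
    """

    name: str
    chemical_class: str
    polarity: str = Field(default="positive", pattern="^(positive|negative)$")
    calibration_matrix: str = "milk"
    internal_standard: Optional[str] = None
    guidance: Optional[GuidanceValue] = None
    blank_correct: bool = False
    is_conjugate: bool = False

    @field_validator("chemical_class")
    @classmethod
    def _class_known(cls, v: str) -> str:
        if v not in CHEMICAL_CLASSES:
            raise ValueError(
                f"unknown chemical_class {v!r}; allowed: {', '.join(CHEMICAL_CLASSES)}"
            )
        return v

    @field_validator("calibration_matrix")
    @classmethod
    def _matrix_known(cls, v: str) -> str:
        if v not in ("urine", "serum", "milk", "solvent"):
            raise ValueError(f"calibration_matrix must be urine|serum|milk|solvent, got {v!r}")
        return v


class SampleMeta(BaseModel):
    """Per-sample metadata: preparation volume and optional covariate."""

    sample_id: str
    subject_id: str = ""
    volume_used: float = Field(default=200.0, gt=0, description="uL")
    covariate_name: Optional[str] = None
    covariate_value: Optional[float] = None
    collection_day: int = 0


class CalibrationCurve(BaseModel):
    """Fitted weighted calibration line for one analyte in one matrix."""

    analyte: str
    matrix: str
    slope: float
    intercept: float
    r2: float
    weighting: str = Field(default="inverse_x", pattern="^(none|inverse_x)$")
    range_min: float
    range_max: float
    used_is: bool = False
    n_points: int

    @model_validator(mode="after")
    def _usable(self) -> "CalibrationCurve":
        if self.slope == 0:
            raise ValueError(f"unusable calibration for {self.analyte}/{self.matrix}: zero slope")
        if self.range_min > self.range_max:
            raise ValueError("calibration range inverted")
        return self


class SensitivityEstimate(BaseModel):
    """LOD/LOQ estimate for one analyte in one matrix (ng/mL)."""

    analyte: str
    matrix: str
    lod: float = Field(gt=0)
    loq: float = Field(gt=0)
    method: str = Field(pattern="^(lowest-level|interpolated)$")

    @model_validator(mode="after")
    def _ordered(self) -> "SensitivityEstimate":
        if self.lod > self.loq:
            raise ValueError("LOD must not exceed LOQ")
        return self


class TruthRecord(BaseModel):
    """Ground truth of the synthetic instrument model for one analyte/matrix.

    ``loq_true`` is derived in closed form: with the noise model
    ``sd(area) = sqrt((cv*mu)^2 + floor^2)`` and S/N defined against the
    noise floor, S/N = 10 at conc = 10*floor/slope_matrix.
    """

    analyte: str
    matrix: str
    true_slope: float = Field(gt=0)
    true_intercept: float = 0.0
    sse_true: float = Field(default=1.0, gt=0)
    recovery_true: float = Field(default=1.0, gt=0, le=1.2)
    noise_floor: float = Field(default=0.0, ge=0)
    noise_cv: float = Field(default=0.0, ge=0)
    contamination_conc: float = Field(default=0.0, ge=0)

    @property
    def matrix_slope(self) -> float:
        """Effective matrix-matched slope (solvent slope x SSE)."""
        return self.true_slope * self.sse_true

    @property
    def loq_true(self) -> float:
        """Concentration with expected S/N = 10 under the noise model."""
        if self.noise_floor == 0:
            raise ValueError("LOQ undefined without a noise floor")
        return 10.0 * self.noise_floor / self.matrix_slope

    @property
    def lod_true(self) -> float:
        """Concentration with expected S/N = 3 under the noise model."""
        if self.noise_floor == 0:
            raise ValueError("LOD undefined without a noise floor")
        return 3.0 * self.noise_floor / self.matrix_slope


class ExposureProfile(BaseModel):
    """Generative description of one analyte's longitudinal exposure."""

    analyte: str
    dynamics: str = Field(default="constant", pattern="^(constant|episodic|accumulating)$")
    median_conc: float = Field(gt=0)
    dispersion: float = Field(default=0.0, ge=0, description="log-scale sd")
    detection_prob: float = Field(default=1.0, ge=0, le=1)
    correlation_group: Optional[str] = None
    reporting_limit: float = Field(default=0.0, ge=0)


class ExposureAssessment(BaseModel):
    """One row of the infant high-exposure risk table."""

    analyte: str
    chemical_class: str = ""
    assumed_conc: float = Field(ge=0, description="ng/mL")
    assumed_from: str = Field(pattern="^(max_quantified|loq)$")
    hubi: float = Field(ge=0, description="ug/kg bw/day")
    guidance_kind: str = "none"
    guidance_adult: Optional[float] = None
    guidance_infant: Optional[float] = None
    ratio: Optional[float] = None
    ratio_compat: Optional[float] = None
    moe: Optional[float] = None
    moe_compat: Optional[float] = None
    concern: Optional[bool] = None


class PairedComparison(BaseModel):
    """Summary of a treated-vs-untreated paired measurement comparison."""

    analyte: str
    n_pairs: int
    median_ratio: float
    n_excluded: int = 0
    note: str = ""
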