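"""Delimited-file readers and writers and the panel-config loader.

All tables are comma-separated UTF-8 with a header row and "." decimal.
Concentrations are ng/mL throughout; intakes are converted to ug/kg bw/day
only at the exposure boundary.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import ValidationError

from .types import (
    AnalyteSpec,
    PEAK_COLUMNS,
    QUANT_COLUMNS,
    ROLES_WITH_NOMINAL,
    Role,
)

log = logging.getLogger("xenoquant")

_MANDATORY = ["sample_id", "analyte", "matrix", "role", "area"]
_FLOAT_PRECISION = "%.10g"


class PeakTableError(ValueError):
    """Raised for malformed peak-measurement tables."""


def read_peak_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a peak-measurement table, enforcing the schema invariants.

    Returns a DataFrame with the :data:`~xenoquant.types.PEAK_COLUMNS`
    schema. Raises :class:`PeakTableError` naming the offending column or
    the offending rows (by sample_id) on invariant violations.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "analyte": str, "batch": str})
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise PeakTableError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in PEAK_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[PEAK_COLUMNS]
    return validate_peak_table(df)


def validate_peak_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check peak-table invariants; return the table unchanged if valid."""
    bad_role = ~df["role"].isin([r.value for r in Role])
    if bad_role.any():
        raise PeakTableError(
            f"unknown role(s) {sorted(df.loc[bad_role, 'role'].unique())}"
        )
    if (df["area"] < 0).any():
        rows = df.loc[df["area"] < 0, "sample_id"].tolist()
        raise PeakTableError(f"negative area for sample_id(s): {rows}")
    needs_nominal = df["role"].isin(ROLES_WITH_NOMINAL)
    missing_nom = needs_nominal & df["nominal_conc"].isna()
    if missing_nom.any():
        rows = df.loc[missing_nom, "sample_id"].tolist()
        raise PeakTableError(
            f"role requires nominal_conc but none given for sample_id(s): {rows}"
        )
    dup = df.duplicated(subset=["sample_id", "analyte"])
    if dup.any():
        rows = df.loc[dup, ["sample_id", "analyte"]].itertuples(index=False)
        raise PeakTableError(
            "duplicate (sample_id, analyte) pairs: "
            + ", ".join(f"({s}, {a})" for s, a in rows)
        )
    return df


def write_peak_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a peak table; round-trips losslessly through read_peak_table."""
    df[PEAK_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_PRECISION)


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write any report table with the project's numeric precision."""
    df.to_csv(path, index=False, float_format=_FLOAT_PRECISION)


def read_quant_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "analyte": str, "status": str})
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(f"missing quantitation column(s): {', '.join(missing)}")
    return df[QUANT_COLUMNS]


def load_panel(path: Union[str, Path]) -> list[AnalyteSpec]:
    """Load an analyte panel from a YAML config.

    The file maps ``analytes`` to a list of entries; each entry carries the
    identity, class, calibration matrix, optional internal-standard link,
    optional guidance value and the blank-correction flag.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw or "analytes" not in raw or not raw["analytes"]:
        raise ValueError(f"empty panel: {path}")
    specs: list[AnalyteSpec] = []
    seen: set[str] = set()
    for entry in raw["analytes"]:
        try:
            spec = AnalyteSpec(**entry)
        except ValidationError as exc:
            raise ValueError(f"invalid panel entry {entry.get('name', '?')!r}: {exc}") from exc
        if spec.name in seen:
            raise ValueError(f"duplicate analyte name: {spec.name}")
        seen.add(spec.name)
        specs.append(spec)
    return specs


def panel_to_dict(panel: Sequence[AnalyteSpec]) -> dict:
    return {"analytes": [s.model_dump(exclude_none=True) for s in panel]}


def save_panel(panel: Sequence[AnalyteSpec], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(panel_to_dict(panel), fh, sort_keys=False)


def builtin_panel_path(name: str = "exposure_registry.yaml") -> Path:
    """Path of a panel config shipped with the package."""
    return Path(__file__).parent / "data" / name
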