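"""Reading and writing the study tables (CSV, UTF-8, "." decimal).

Two input schemas:

measurements
    ``chemical, temperature_C, vial_total_mL, fill_mL, replicate, area``
    -- one row per vial replicate.  Temperatures are degC at the interface
    and Kelvin internally; the headspace/solution ratio is derived from the
    two volumes.

predictions
    ``chemical, model, log10_kaw, in_domain[, uncertainty_lo, uncertainty_hi]``
    -- one row per (chemical, in-silico model).

Malformed rows are reported with their file line numbers in a single
:class:`ValidationError` rather than failing on the first offence.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .comparison import PredictionRecord
from .estimation import VialObservation

__all__ = [
    "ValidationError",
    "MEASUREMENT_COLUMNS",
    "PREDICTION_COLUMNS",
    "read_measurements",
    "read_measurements_frame",
    "write_measurements",
    "read_predictions",
]

MEASUREMENT_COLUMNS = (
    "chemical",
    "temperature_C",
    "vial_total_mL",
    "fill_mL",
    "replicate",
    "area",
)
PREDICTION_COLUMNS = ("chemical", "model", "log10_kaw", "in_domain")

CELSIUS_OFFSET = 273.15


class ValidationError(ValueError):
    """Input table failed validation; ``problems`` lists one message per row."""

    def __init__(self, path, problems: list[str]):
        self.path = str(path)
        self.problems = problems
        preview = "\n  ".join(problems[:20])
        more = f"\n  ... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__(f"invalid table {self.path}:\n  {preview}{more}")


def _read_csv_ci(path, required: tuple[str, ...]) -> pd.DataFrame:
    """Read a CSV, matching required column names case-insensitively."""
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in required if c.lower() not in lower]
    if missing:
        raise ValidationError(path, [f"missing required column(s): {missing}"])
    return df.rename(columns={lower[c.lower()]: c for c in required if lower[c.lower()] != c})


def read_measurements_frame(path) -> pd.DataFrame:
    """Read and validate the measurements table; unknown columns preserved."""
    df = _read_csv_ci(path, MEASUREMENT_COLUMNS)
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            total = float(row["vial_total_mL"])
            fill = float(row["fill_mL"])
            area = float(row["area"])
            temp = float(row["temperature_C"])
            rep = int(row["replicate"])
        except (TypeError, ValueError):
            problems.append(f"line {line}: non-numeric value")
            continue
        if not str(row["chemical"]).strip():
            problems.append(f"line {line}: empty chemical id")
        if total <= 0 or fill <= 0:
            problems.append(f"line {line}: non-positive volume")
        elif fill > total:
            problems.append(
                f"line {line}: fill_mL {fill} exceeds vial_total_mL {total}"
            )
        if area <= 0 or not math.isfinite(area):
            problems.append(f"line {line}: non-positive area {area}")
        if temp + CELSIUS_OFFSET <= 0:
            problems.append(f"line {line}: temperature below absolute zero")
        if rep < 1:
            problems.append(f"line {line}: replicate index must be >= 1")
    if problems:
        raise ValidationError(path, problems)
    return df


def read_measurements(path) -> list[VialObservation]:
    """Parse the measurements table into replicate-level observations."""
    df = read_measurements_frame(path)
    obs = []
    for _, row in df.iterrows():
        total = float(row["vial_total_mL"])
        fill = float(row["fill_mL"])
        obs.append(
            VialObservation(
                chemical=str(row["chemical"]).strip(),
                temperature=float(row["temperature_C"]) + CELSIUS_OFFSET,
                ratio=(total - fill) / fill,
                replicate=int(row["replicate"]),
                area=float(row["area"]),
            )
        )
    return obs


def write_measurements(frame: pd.DataFrame, path) -> None:
    """Write a measurements table (schema-checked) to CSV."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"measurements frame lacks columns {missing}")
    frame.to_csv(path, index=False)


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_flag(value, line: int, problems: list[str]) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    problems.append(f"line {line}: unparseable in_domain flag {value!r}")
    return True


def read_predictions(path) -> list[PredictionRecord]:
    """Parse the in-silico predictions table."""
    df = _read_csv_ci(path, PREDICTION_COLUMNS)
    problems: list[str] = []
    records: list[PredictionRecord] = []
    has_unc = {"uncertainty_lo", "uncertainty_hi"} <= set(df.columns)
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            val = float(row["log10_kaw"])
        except (TypeError, ValueError):
            problems.append(f"line {line}: non-numeric log10_kaw")
            continue
        if not math.isfinite(val):
            problems.append(f"line {line}: non-finite log10_kaw")
            continue
        unc = None
        if has_unc and not (
            pd.isna(row["uncertainty_lo"]) or pd.isna(row["uncertainty_hi"])
        ):
            unc = (float(row["uncertainty_lo"]), float(row["uncertainty_hi"]))
        try:
            records.append(
                PredictionRecord(
                    chemical=str(row["chemical"]).strip(),
                    model=str(row["model"]).strip(),
                    log10_kaw=val,
                    in_domain=_parse_flag(row["in_domain"], line, problems),
                    uncertainty=unc,
                )
            )
        except ValueError as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ValidationError(path, problems)
    return records
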