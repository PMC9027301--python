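"""Readers, writers and run configuration.

CSV dialect: UTF-8, comma-separated, "." decimal point, times as decimal
hours (impedance) or minutes (OCR).  Floats are written with ``%.10g`` so
repeated runs with the same seed produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bioenergetics import OCRTrace
from .synthetic import LDHPlate

__all__ = [
    "IMPEDANCE_COLUMNS",
    "OCR_COLUMNS",
    "RunConfig",
    "SchemaError",
    "read_impedance_csv",
    "write_impedance_csv",
    "read_ocr_csv",
    "write_ocr_csv",
    "write_ldh_csv",
    "read_ldh_csv",
]

IMPEDANCE_COLUMNS = ("time_h", "well", "group", "frequency_hz",
                     "z_real_ohm", "z_imag_ohm")
OCR_COLUMNS = ("time_min", "well", "dose_uM", "ocr_pmol_min")
FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    """A tabular input violates its schema; the message names the column/rows."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric values in column {col!r} at rows "
                f"{list(bad[:5])}"
            )
        if coerced.isna().any():
            rows = list(df.index[coerced.isna()][:5])
            raise SchemaError(f"{path}: missing values in column {col!r} "
                              f"at rows {rows}")
        df[col] = coerced
    return df


def read_impedance_csv(path) -> pd.DataFrame:
    """Read long-format multifrequency impedance records.

    Required columns: ``time_h, well, group, frequency_hz, z_real_ohm,
    z_imag_ohm``.  Duplicate (well, time, frequency) rows are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, IMPEDANCE_COLUMNS, path)
    df = _numeric(df, ("time_h", "frequency_hz", "z_real_ohm", "z_imag_ohm"),
                  path)
    dup = df.duplicated(subset=["well", "time_h", "frequency_hz"])
    if dup.any():
        rows = list(df.index[dup][:5])
        raise SchemaError(
            f"{path}: duplicate (well, time_h, frequency_hz) rows, e.g. {rows}"
        )
    return df[list(IMPEDANCE_COLUMNS)]


def write_impedance_csv(df: pd.DataFrame, path) -> None:
    df[list(IMPEDANCE_COLUMNS)].to_csv(path, index=False,
                                       float_format=FLOAT_FORMAT)


def read_ocr_csv(path, injections: dict[str, float]) -> list[OCRTrace]:
    """Read OCR traces; the injection schedule comes from configuration."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, OCR_COLUMNS, path)
    df = _numeric(df, ("time_min", "dose_uM", "ocr_pmol_min"), path)
    traces = []
    for well, sub in df.groupby("well", sort=True):
        sub = sub.sort_values("time_min")
        traces.append(OCRTrace(
            times_min=tuple(sub["time_min"]),
            ocr_pmol_min=tuple(sub["ocr_pmol_min"]),
            injections=dict(injections),
            well=str(well),
            dose_um=float(sub["dose_uM"].iloc[0]),
        ))
    return traces


def write_ocr_csv(traces: list[OCRTrace], path) -> None:
    rows = [
        {"time_min": t, "well": tr.well, "dose_uM": tr.dose_um,
         "ocr_pmol_min": v}
        for tr in traces for t, v in zip(tr.times_min, tr.ocr_pmol_min)
    ]
    pd.DataFrame(rows, columns=list(OCR_COLUMNS)).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def write_ldh_csv(plate: LDHPlate, path) -> None:
    rows = []
    for dose, values in plate.samples.items():
        for i, v in enumerate(values, 1):
            rows.append({"role": "sample", "dose_uM": dose, "replicate": i,
                         "absorbance": v})
    for role, values in (("spontaneous", plate.spontaneous),
                         ("maximum", plate.maximum)):
        for i, v in enumerate(values, 1):
            rows.append({"role": role, "dose_uM": np.nan, "replicate": i,
                         "absorbance": v})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_ldh_csv(path) -> LDHPlate:
    df = pd.read_csv(path)
    _require_columns(df, ("role", "dose_uM", "replicate", "absorbance"), path)
    samples = {
        float(dose): tuple(sub.sort_values("replicate")["absorbance"])
        for dose, sub in df[df["role"] == "sample"].groupby("dose_uM")
    }
    spont = tuple(df.loc[df["role"] == "spontaneous", "absorbance"])
    maxi = tuple(df.loc[df["role"] == "maximum", "absorbance"])
    return LDHPlate(samples=samples, spontaneous=spont, maximum=maxi)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a pipeline run.

    ``frequency`` is ``"auto"`` (select per quantity from the t = 0 ratio
    spectra) or a fixed frequency in Hz applied to every quantity.
    When ``impedance_csv`` is None a synthetic experiment is generated.
    """

    seed: int = 0
    outdir: str = "results"
    impedance_csv: str | None = None
    ocr_csv: str | None = None
    ldh_csv: str | None = None
    frequency: str | float = "auto"
    auc_start_h: float = 0.0
    auc_end_h: float = 25.0
    noise_fraction: float = 0.01
    wells_per_group: int = 6
    sample_interval_h: float = 0.25
    rb_zero_threshold: float = 0.4
    dwell_h: float = 1.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.frequency, str) and self.frequency != "auto":
            raise ValueError("frequency must be 'auto' or a number in Hz")
        if not self.auc_start_h < self.auc_end_h:
            raise ValueError("auc_start_h must be < auc_end_h")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load from a YAML mapping; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
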