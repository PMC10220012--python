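"""Readers/writers for the delimited table formats.

Dialect: comma-separated, UTF-8, '.' decimal, ISO header names.  Unknown
columns are preserved as passthrough.  Output tables carry a provenance
header (comment lines) with the config hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from limnoflux.agemodel import DATE_TYPES, validate_date_table
from limnoflux.calibration import CalibrationCurve
from limnoflux.errors import DataError, SchemaError

__all__ = [
    "ValidationReport",
    "read_date_table",
    "read_proxy_table",
    "read_diatom_table",
    "read_calibration_curve",
    "write_table",
    "read_table",
]

PROXY_REQUIRED = ("depth", "toc", "tic")
PROXY_NUMERIC = (
    "depth", "toc", "tic", "d13c", "cn", "density", "sand", "silt", "clay",
    "biosi", "chlorophyll",
)


@dataclass
class ValidationReport:
    """Row-level validation findings; ``errors`` abort, ``flags`` do not."""

    source: str
    errors: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_on_error(self) -> None:
        if self.errors:
            raise DataError(f"{self.source}: " + "; ".join(self.errors))


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise SchemaError(f"file not found: {path}") from None


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, cols, path, report: ValidationReport) -> None:
    for c in cols:
        if c not in df.columns:
            continue
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        for i in df.index[bad]:
            report.errors.append(f"row {i}: non-numeric value {df.at[i, c]!r} in '{c}'")
        df[c] = coerced


def read_date_table(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Dated horizons: columns labID, age, error, depth, type[, excluded]."""
    df = _read_csv(path)
    _require_columns(df, ("labID", "age", "error", "depth", "type"), path)
    report = ValidationReport(str(path))
    _coerce_numeric(df, ("age", "error", "depth"), path, report)
    bad_type = set(df["type"].dropna()) - DATE_TYPES
    if bad_type:
        report.errors.append(f"unknown date type(s) {sorted(bad_type)}")
    report.raise_on_error()
    return validate_date_table(df), report


def read_proxy_table(path, require_density: bool = False) -> tuple[pd.DataFrame, ValidationReport]:
    """Depth-resolved proxy table; flags closure and grain-size violations."""
    df = _read_csv(path)
    _require_columns(df, PROXY_REQUIRED, path)
    if require_density and "density" not in df.columns:
        raise SchemaError(f"{path}: missing 'density' column and no fallback configured")
    report = ValidationReport(str(path))
    _coerce_numeric(df, PROXY_NUMERIC, path, report)
    report.raise_on_error()

    closure = df["toc"].fillna(0) + df["tic"].fillna(0)
    for i in df.index[closure > 100]:
        report.flags.append(f"row {i}: TOC+TIC = {closure[i]:.2f} exceeds 100")
    if (df["toc"] < 0).any() or (df["tic"] < 0).any():
        report.errors.append("negative TOC or TIC")
    if {"sand", "silt", "clay"} <= set(df.columns):
        gs = df[["sand", "silt", "clay"]].sum(axis=1)
        for i in df.index[(gs - 100).abs() > 0.5]:
            report.flags.append(f"row {i}: grain-size fractions sum to {gs[i]:.2f}")
    if "density" in df.columns and (df["density"] <= 0).any():
        report.errors.append("non-positive dry bulk density")
    report.raise_on_error()
    return df, report


def read_diatom_table(path) -> tuple[pd.DataFrame, ValidationReport]:
    df = _read_csv(path)
    _require_columns(df, ("depth",), path)
    report = ValidationReport(str(path))
    _coerce_numeric(df, tuple(df.columns), path, report)
    report.raise_on_error()
    return df, report


def read_calibration_curve(path, name: str | None = None) -> CalibrationCurve:
    """Three-column curve (cal BP, 14C age, error); header and comma or
    whitespace separation are both accepted."""
    p = Path(path)
    try:
        df = pd.read_csv(p, comment="#", sep=None, engine="python")
    except FileNotFoundError:
        raise SchemaError(f"file not found: {path}") from None
    if df.shape[1] < 3:
        raise SchemaError(f"{path}: calibration curve needs 3 columns")
    # tolerate header-less files
    first = df.columns[0]
    try:
        float(first)
        df = pd.read_csv(p, comment="#", sep=None, engine="python", header=None)
    except ValueError:
        pass
    arr = df.iloc[:, :3].apply(pd.to_numeric, errors="coerce").dropna().to_numpy(float)
    if arr.shape[0] < 2:
        raise SchemaError(f"{path}: too few usable curve rows")
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2], name=name or p.stem)


# ---------------------------------------------------------------------------
# provenance-stamped writing


def provenance_header(config_hash: str, seed, stage: str) -> str:
    from limnoflux import __version__

    return (
        f"# limnoflux v{__version__} stage={stage} seed={seed} "
        f"config={config_hash}\n"
    )


def write_table(df: pd.DataFrame, path, config_hash: str = "-", seed="-", stage: str = "-") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(provenance_header(config_hash, seed, stage))
    df.to_csv(buf, index=False, float_format="%.10g")
    path.write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return _read_csv(path)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
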