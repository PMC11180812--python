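"""Cohort CSV readers/writers, coefficient JSON, and configuration handling.

The interchange format is a plain comma-separated, UTF-8, header-row CSV
with one vessel per row. Required pressure columns are validated on read;
rows with unparseable or non-physical cells are *flagged*, never dropped,
so a cohort run always accounts for every input row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .constants import PhysicalConstants
from .prediction import PredictionCoefficients

REQUIRED_PRESSURE_COLS = ["vessel_id", "Pa_rest", "Pd_rest", "Pa_hyp", "Pd_hyp"]
OPTIONAL_NUMERIC_COLS = [
    "height_cm",
    "len_prox_mm", "diam_prox_mm",
    "len_sten_mm", "diam_sten_mm",
    "len_dist_mm", "diam_dist_mm",
    "ref_diam_mm", "as_percent",
    "apv_rest", "apv_hyp",
]
GEOMETRY_COLS = [
    "len_prox_mm", "diam_prox_mm",
    "len_sten_mm", "diam_sten_mm",
    "len_dist_mm", "diam_dist_mm",
]
PRESSURE_VALUE_COLS = ["Pa_rest", "Pd_rest", "Pa_hyp", "Pd_hyp"]

CSV_FLOAT_FORMAT = "%.6g"


class CohortSchemaError(ValueError):
    """The cohort file cannot be interpreted at all (e.g. missing column)."""


def _append_flag(flags: pd.Series, mask: pd.Series, flag: str) -> pd.Series:
    add = mask.map(lambda m: flag if m else "")
    return flags.where(~mask, flags.str.cat(add, sep=";").str.strip(";"))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`CohortSchemaError` naming the first missing required
    column. Cell-level problems (unparseable numbers, non-positive
    pressures, out-of-range heights) set per-row entries in a ``flags``
    column instead of failing the load.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in REQUIRED_PRESSURE_COLS:
        if col not in df.columns:
            raise CohortSchemaError(f"{path.name}: missing required column {col!r}")
    if df["vessel_id"].duplicated().any():
        dup = df.loc[df["vessel_id"].duplicated(), "vessel_id"].iloc[0]
        raise CohortSchemaError(f"{path.name}: duplicate vessel_id {dup!r}")

    numeric_cols = [c for c in PRESSURE_VALUE_COLS + OPTIONAL_NUMERIC_COLS if c in df.columns]
    flags = pd.Series("", index=df.index, dtype=str)
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        flags = _append_flag(flags, bad, f"unparseable_{col}")
        df[col] = coerced

    for col in PRESSURE_VALUE_COLS:
        bad = df[col].isna() | (df[col] <= 0)
        flags = _append_flag(flags, bad, f"invalid_{col}")
    if "height_cm" in df.columns:
        flags = _append_flag(flags, df["height_cm"].abs() >= 25, "height_out_of_range")
    else:
        df["height_cm"] = 0.0

    if "flags" in df.columns:
        prior = df["flags"].fillna("").astype(str)
        flags = (prior.str.cat(flags, sep=";")).str.strip(";")
    df["flags"] = flags
    return df


def write_cohort(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a cohort CSV with canonical float formatting.

    ``header_comment`` lines (e.g. the run configuration) are prefixed
    with ``#`` so :func:`read_cohort` skips them.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=CSV_FLOAT_FORMAT)


def has_geometry(df: pd.DataFrame) -> bool:
    """True when every 3D-QCA geometry column is present."""
    return all(col in df.columns for col in GEOMETRY_COLS)


def has_doppler(df: pd.DataFrame) -> bool:
    return "apv_rest" in df.columns and "apv_hyp" in df.columns


def write_coefficients(
    coefs: PredictionCoefficients,
    path: str | Path,
    fit_info: dict[str, Any] | None = None,
) -> None:
    """Serialize a coefficient set (plus optional fit statistics) to JSON."""
    payload: dict[str, Any] = dataclasses.asdict(coefs)
    if fit_info:
        payload["fit_info"] = fit_info
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_coefficients(path: str | Path) -> PredictionCoefficients:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    payload.pop("fit_info", None)
    return PredictionCoefficients(**payload)


def load_constants(path: str | Path | None) -> PhysicalConstants:
    """Physical constants from a YAML/JSON mapping; defaults when ``path`` is None."""
    if path is None:
        return PhysicalConstants()
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {f.name for f in dataclasses.fields(PhysicalConstants)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown constants in {path}: {sorted(unknown)}")
    return PhysicalConstants(**payload)


def constants_comment(constants: PhysicalConstants) -> str:
    """One-line provenance string echoed into output file headers."""
    fields = dataclasses.asdict(constants)
    return "constants: " + ", ".join(f"{k}={v:g}" for k, v in fields.items())
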