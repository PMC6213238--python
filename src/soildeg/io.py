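"""Delimited-text dataset readers with schema validation.

All pipeline inputs are plain CSV with a header.  Each schema names its
required columns, optional columns and unit conversions (temperatures are
accepted in degC and stored in K where the physics needs absolute
temperature).  Validation failures are collected per row and reported with
line numbers so a single pass over a file surfaces every problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["SCHEMAS", "load_dataset", "logger"]

logger = logging.getLogger("soildeg")
if not logger.handlers:  # stderr by default; computation results never go here
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s soildeg: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.WARNING)


@dataclass(frozen=True)
class Schema:
    name: str
    required: tuple[str, ...]
    optional: tuple[str, ...] = ()
    #: column -> (new column, conversion) applied after validation
    conversions: dict[str, tuple[str, Callable]] = None  # type: ignore[assignment]


def _c_to_k(v):
    return v + 273.15


SCHEMAS: dict[str, Schema] = {
    "incubation": Schema(
        "incubation",
        required=("dx_percent", "v_gas_ml", "temp_c", "pressure_pa", "mass_kg", "dt_h"),
        conversions={"temp_c": ("temp_k", _c_to_k)},
    ),
    "mass_loss": Schema("mass_loss", required=("time_years", "value_percent")),
    "response_grid": Schema("response_grid", required=("temp_c", "w_rel", "u_m")),
    "rate_temperature": Schema("rate_temperature", required=("temp_c", "k_per_year")),
    "forcing": Schema("forcing", required=("time_h", "temp_c"), optional=("w_rel",)),
    "depth_profile": Schema("depth_profile", required=("depth_cm", "u_m")),
    "wrc": Schema("wrc", required=("pressure_kpa", "theta_percent")),
}


def load_dataset(path: str | Path, schema: str | Schema) -> pd.DataFrame:
    """Read and validate a delimited dataset against a named schema.

    Lines starting with '#' are treated as comments (truth headers from the
    synthetic generators pass through untouched).  Raises
    :class:`SchemaError` listing missing columns or, for cell-level
    problems, every offending line by its 1-based file line number.
    """
    if isinstance(schema, str):
        try:
            schema = SCHEMAS[schema]
        except KeyError:
            raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")

    # map dataframe rows back to file line numbers (header + comments shift them)
    lines = path.read_text().splitlines()
    data_line_numbers = []
    header_seen = False
    for i, line in enumerate(lines, start=1):
        if line.startswith("#") or not line.strip():
            continue
        if not header_seen:
            header_seen = True
            continue
        data_line_numbers.append(i)

    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = set(schema.required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")

    cols = [c for c in (*schema.required, *(schema.optional or ())) if c in df.columns]
    problems: list[str] = []
    out = {}
    for col in cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        for row_idx in np.flatnonzero(bad.to_numpy()):
            ln = data_line_numbers[row_idx] if row_idx < len(data_line_numbers) else "?"
            problems.append(f"line {ln}: non-numeric {col}={df[col].iloc[row_idx]!r}")
        if numeric.isna().any() and not bad.any():
            for row_idx in np.flatnonzero(numeric.isna().to_numpy()):
                ln = data_line_numbers[row_idx] if row_idx < len(data_line_numbers) else "?"
                problems.append(f"line {ln}: missing {col}")
        out[col] = numeric
    if problems:
        raise SchemaError(
            f"{path.name}: {len(problems)} invalid cell(s): " + "; ".join(problems),
            lines=problems,
        )

    result = pd.DataFrame(out)
    for src, (dst, fn) in (schema.conversions or {}).items():
        if src in result.columns:
            result[dst] = fn(result[src])
    return result
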