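"""Table and outline file I/O.

Species tables are comma-separated UTF-8 CSV with a required header.
Loading is all-or-nothing: any invalid row aborts the load and the error
lists every offending row with its line number, so no taxon is ever
silently dropped (small-n morphometrics is sensitive to silent
exclusions).

Outline files are plain-text two-column x,y coordinates in mm, one vertex
per line, implicitly closed; the radius split polyline lives in a
companion file with the ``.radius`` suffix.
"""

from __future__ import annotations

import os
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import TableLoadError
from .morphometry import DESCRIPTOR_NAMES, WingOutline

__all__ = [
    "REQUIRED_COLUMNS",
    "read_species_table",
    "write_species_table",
    "read_outline",
    "write_outline",
]

REQUIRED_COLUMNS = (
    "taxon_id", "subfamily", "is_mimicking", "is_pterochrozinae",
) + DESCRIPTOR_NAMES

_RAW_COLUMNS = (
    "length_max", "width_mid", "width_anterior_field",
    "width_posterior_field", "area_total", "area_anterior",
    "area_posterior", "perimeter_total", "perimeter_anterior",
    "perimeter_posterior",
)


def read_species_table(path: str) -> pd.DataFrame:
    """Load and validate a species table; refuse partial loads.

    Checks: required header, unique taxon ids, numeric descriptor cells,
    positive descriptors, circularity <= 1, and positivity of any raw
    measurement columns present. Every violation is reported with its
    CSV line number (header = line 1).
    """
    try:
        table = pd.read_csv(path, sep=",", encoding="utf-8")
    except Exception as exc:
        raise TableLoadError(f"cannot parse {path!r}: {exc}") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TableLoadError(f"{path}: missing required columns {missing}")

    problems: List[str] = []
    dup = table["taxon_id"][table["taxon_id"].duplicated(keep=False)]
    for idx in dup.index:
        problems.append(f"line {idx + 2}: duplicate taxon_id "
                        f"{table.at[idx, 'taxon_id']!r}")

    numeric_cols = list(DESCRIPTOR_NAMES) + [
        c for c in _RAW_COLUMNS + ("thorax_height",) if c in table.columns]
    for col in numeric_cols:
        values = pd.to_numeric(table[col], errors="coerce")
        for idx in table.index[values.isna() & table[col].notna()]:
            problems.append(f"line {idx + 2}, column {col!r}: "
                            f"non-numeric cell {table.at[idx, col]!r}")
        for idx in table.index[values.isna() & table[col].isna()]:
            if col in DESCRIPTOR_NAMES:
                problems.append(f"line {idx + 2}, column {col!r}: "
                                "missing value")
        with np.errstate(invalid="ignore"):
            bad = values.notna() & (values <= 0)
        for idx in table.index[bad]:
            problems.append(f"line {idx + 2}, column {col!r}: "
                            f"non-positive value {values[idx]!r}")
        table[col] = values

    circ = table["circularity_anterior"]
    for idx in table.index[circ.notna() & (circ > 1.0 + 1e-9)]:
        problems.append(f"line {idx + 2}: circularity_anterior "
                        f"{circ[idx]!r} exceeds the isoperimetric bound 1")

    for col in ("is_mimicking", "is_pterochrozinae"):
        coerced = _coerce_bool(table[col])
        for idx in table.index[coerced.isna()]:
            problems.append(f"line {idx + 2}, column {col!r}: "
                            f"not a boolean: {table.at[idx, col]!r}")
        table[col] = coerced

    if problems:
        raise TableLoadError(
            f"{path}: {len(problems)} invalid row(s); load refused "
            "(all-or-nothing):\n" + "\n".join(problems))
    table["is_mimicking"] = table["is_mimicking"].astype(bool)
    table["is_pterochrozinae"] = table["is_pterochrozinae"].astype(bool)
    if "leaf_like" in table.columns:
        table["leaf_like"] = _coerce_bool(table["leaf_like"]).astype(bool)
    return table


def _coerce_bool(series: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}

    def convert(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, np.integer)) and v in (0, 1):
            return bool(v)
        if isinstance(v, str) and v.strip().lower() in mapping:
            return mapping[v.strip().lower()]
        return None

    return series.map(convert)


def write_species_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False, encoding="utf-8")


def read_outline(path: str, taxon_id: Optional[str] = None) -> WingOutline:
    """Read a two-column x,y outline plus its ``.radius`` companion."""
    vertices = np.loadtxt(path, dtype=float, ndmin=2)
    radius_path = path + ".radius"
    split = (np.loadtxt(radius_path, dtype=float, ndmin=2)
             if os.path.exists(radius_path) else None)
    name = taxon_id or os.path.splitext(os.path.basename(path))[0]
    return WingOutline(vertices=vertices, split_polyline=split,
                       taxon_id=name)


def write_outline(outline: WingOutline, path: str) -> None:
    np.savetxt(path, outline.vertices, fmt="%.8f")
    if outline.split_polyline is not None:
        np.savetxt(path + ".radius", outline.split_polyline, fmt="%.8f")
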