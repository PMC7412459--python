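"""CSV reading/writing and record validation.

The record schema mirrors how leaf surveys are tabulated: one row per leaf
spot with a sample id, pigment readings in exactly one representation — raw
meter units (spad, aci) or transformed units (srs, lba) — and optionally the
CIELab triples of one or both surfaces (L_D, a_D, b_D / L_B, a_B, b_B) and
observed quasi-color coordinates (qL, qa, qb).  Files are plain UTF-8 CSV
with a mandatory header and decimal points.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .pigments import aci_to_lba, spad_to_srs

__all__ = ["RecordValidationError", "read_records", "write_records"]

_SURFACE_COLS = {
    "adaxial": ("L_D", "a_D", "b_D"),
    "abaxial": ("L_B", "a_B", "b_B"),
}
_CMQ_COLS = ("qL", "qa", "qb")


class RecordValidationError(ValueError):
    """One or more rows failed validation; ``errors`` lists (row, message)."""

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"invalid records: {lines}{more}")


def read_records(
    path: Union[str, Path], pigment_representation: str = "auto"
) -> pd.DataFrame:
    """Read and validate a leaf-record CSV.

    Always returns transformed ``srs``/``lba`` columns (computing them from
    ``spad``/``aci`` when the file is in raw units).  ``pigment_representation``
    may be ``"raw"``, ``"transformed"`` or ``"auto"``; a file carrying both
    representations is rejected as ambiguous.  Row-level problems are
    collected and reported together with 1-based data row numbers.
    """
    df = pd.read_csv(path)
    has_raw = {"spad", "aci"}.issubset(df.columns)
    has_transformed = {"srs", "lba"}.issubset(df.columns)
    if pigment_representation not in ("auto", "raw", "transformed"):
        raise ValueError("pigment_representation must be 'auto', 'raw' or 'transformed'")
    if has_raw and has_transformed:
        raise RecordValidationError(
            [(0, "both raw (spad/aci) and transformed (srs/lba) pigment columns present")]
        )
    if pigment_representation == "raw" and not has_raw:
        raise RecordValidationError([(0, "missing spad/aci columns")])
    if pigment_representation == "transformed" and not has_transformed:
        raise RecordValidationError([(0, "missing srs/lba columns")])
    if not (has_raw or has_transformed):
        raise RecordValidationError(
            [(0, "no pigment columns: need spad/aci or srs/lba")]
        )

    for surf, cols in _SURFACE_COLS.items():
        present = [c for c in cols if c in df.columns]
        if present and len(present) != 3:
            raise RecordValidationError(
                [(0, f"{surf} surface columns must be all-or-none, found {present}")]
            )

    errors = []
    numeric_cols = [
        c
        for c in df.columns
        if c in {"spad", "aci", "srs", "lba", *_CMQ_COLS}
        or any(c in cols for cols in _SURFACE_COLS.values())
    ]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        for row in np.nonzero(coerced.isna() & df[col].notna())[0]:
            errors.append((int(row) + 1, f"unparseable value {df[col].iloc[row]!r} in {col}"))
        df[col] = coerced

    def check_range(col, lo, hi):
        if col not in df.columns:
            return
        bad = df.index[(df[col] < lo) | (df[col] > hi)]
        for row in bad:
            errors.append(
                (int(row) + 1, f"{col} = {df[col].iloc[row]} outside [{lo}, {hi}]")
            )

    for prefix in ("L_D", "L_B"):
        check_range(prefix, 0.0, 100.0)
    check_range("qL", 0.0, 100.0)
    check_range("spad", 0.0, math.inf)
    check_range("srs", 0.0, math.inf)
    if "aci" in df.columns:
        for row in df.index[df["aci"] <= 0]:
            errors.append((int(row) + 1, f"aci = {df['aci'].iloc[row]} must be positive"))
    if errors:
        raise RecordValidationError(sorted(set(errors)))

    if has_raw:
        df["srs"] = [spad_to_srs(v) for v in df["spad"]]
        df["lba"] = [aci_to_lba(v) for v in df["aci"]]
    return df


def write_records(records: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write records as UTF-8 CSV at full precision."""
    records.to_csv(path, index=False)
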