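"""Cell-table file format: commented-header CSV, plus validation.

The on-disk cell table is plain CSV with one row per cell, preceded by
``#``-comment lines that record provenance (tool, seed, config hash), so any
stage can be re-run from its persisted inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .barcode import CHANNEL_NAMES, parse_code, CodeFormatError
from .classify import CELL_TYPES, LAYERS
from .simulate import CELL_TABLE_COLUMNS

__all__ = [
    "write_cell_table",
    "read_cell_table",
    "validate_cell_table",
    "ValidationReport",
]

_SOMA_SIZES = {"small", "large"}
_ORIENTATIONS = {"toward_IPL", "toward_OPL", "spanning", "none"}

_INTENSITY_COLUMNS = [f"{n}_{c}" for n in CHANNEL_NAMES for c in ("nuc", "cyt")]
_BG_COLUMNS = ([f"bg_mean_{n}" for n in CHANNEL_NAMES]
               + [f"bg_sd_{n}" for n in CHANNEL_NAMES])


def write_cell_table(cells: pd.DataFrame, path, seed: int | None = None,
                     config_hash: str | None = None) -> None:
    """Write a cell table as CSV with a provenance comment header."""
    path = Path(path)
    header = ["# clonetrack cell table"]
    if seed is not None:
        header.append(f"# seed: {seed}")
    if config_hash is not None:
        header.append(f"# config_hash: {config_hash}")
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        cells.to_csv(fh, index=False)


def read_cell_table(path) -> pd.DataFrame:
    """Read a cell table written by :func:`write_cell_table`."""
    df = pd.read_csv(path, comment="#",
                     dtype={"code": "string", "cell_type": "string"})
    for col in ("code", "cell_type"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return df


@dataclass
class ValidationReport:
    """Row-level diagnostics from cell-table validation."""

    n_rows: int
    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return f"cell table OK ({self.n_rows} rows, 0 violations)"
        head = "\n".join(
            f"  row {v['row']}: {v['column']}: {v['message']}"
            for v in self.violations[:20])
        more = ("" if len(self.violations) <= 20
                else f"\n  ... and {len(self.violations) - 20} more")
        return (f"cell table has {len(self.violations)} violation(s) in "
                f"{self.n_rows} rows:\n{head}{more}")


def validate_cell_table(source) -> ValidationReport:
    """Check column presence, ranges and vocabularies of a cell table.

    ``source`` is a path or a DataFrame.  Returns a report listing each
    violation with its row index and column.
    """
    df = source if isinstance(source, pd.DataFrame) else read_cell_table(source)
    violations: list[dict] = []

    def flag(row, column, message):
        violations.append({"row": int(row), "column": column,
                           "message": message})

    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    for col in missing:
        violations.append({"row": -1, "column": col,
                           "message": "required column missing"})
    if missing:
        return ValidationReport(n_rows=len(df), violations=violations)

    if df["cell_id"].duplicated().any():
        for row in df.index[df["cell_id"].duplicated()]:
            flag(row, "cell_id", "duplicate cell id")

    for row, rec in df.iterrows():
        if pd.isna(rec["embryo_id"]) or str(rec["embryo_id"]) == "":
            flag(row, "embryo_id", "missing embryo id")
        if not (pd.notna(rec["section_index"]) and rec["section_index"] >= 0
                and float(rec["section_index"]).is_integer()):
            flag(row, "section_index", "must be a non-negative integer")
        if not (pd.notna(rec["tangential_um"]) and rec["tangential_um"] >= 0):
            flag(row, "tangential_um", "must be >= 0")
        if not (pd.notna(rec["radial_depth_frac"])
                and 0.0 <= rec["radial_depth_frac"] <= 1.0):
            flag(row, "radial_depth_frac", "must lie in [0, 1]")
        if rec["layer"] not in LAYERS:
            flag(row, "layer", f"unknown layer {rec['layer']!r}")
        if rec["soma_size"] not in _SOMA_SIZES:
            flag(row, "soma_size", f"unknown soma size {rec['soma_size']!r}")
        if not 0.0 <= rec["soma_relative_depth"] <= 1.0:
            flag(row, "soma_relative_depth", "must lie in [0, 1]")
        if rec["process_orientation"] not in _ORIENTATIONS:
            flag(row, "process_orientation",
                 f"unknown orientation {rec['process_orientation']!r}")
        for col in _INTENSITY_COLUMNS + _BG_COLUMNS:
            v = rec[col]
            if pd.isna(v) or v < 0:
                flag(row, col, "intensity must be a number >= 0")
        code = rec["code"]
        if isinstance(code, str) and code:
            try:
                parse_code(code)
            except CodeFormatError as e:
                flag(row, "code", str(e))
        ctype = rec["cell_type"]
        if isinstance(ctype, str) and ctype and ctype not in CELL_TYPES:
            flag(row, "cell_type", f"unknown cell type {ctype!r}")

    return ValidationReport(n_rows=len(df), violations=violations)
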