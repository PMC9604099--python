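"""Presence calling: per-cell intensities -> color codes.

Each cell carries 12 mean-intensity measurements (6 channels x
nucleus/cytoplasm) plus per-channel background statistics.  A channel is
positive in a compartment when its measurement clears the background by
``k`` standard deviations; a nuclear call additionally requires the
nucleus/cytoplasm intensity ratio to favour the nucleus (or the cytoplasm to
be negative outright), which guards against cytoplasmic signal bleeding into
the nucleus measurement.  Cells whose called code is empty never entered the
labeling and are dropped before clonal analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .barcode import CHANNEL_NAMES, ColorCode, serialize_code

__all__ = [
    "DEFAULT_K",
    "DEFAULT_NUCLEAR_RATIO_MIN",
    "call_presence",
    "call_cell_code",
    "call_table",
    "filter_labeled",
    "CallingResult",
]

DEFAULT_K = 3.0
DEFAULT_NUCLEAR_RATIO_MIN = 2.0


def call_presence(
    intensity: float,
    background_mean: float,
    background_sd: float,
    k: float = DEFAULT_K,
) -> bool:
    """True iff ``intensity > background_mean + k * background_sd`` (strict)."""
    if intensity < 0 or background_mean < 0 or background_sd < 0:
        raise ValueError("intensities and background statistics must be >= 0")
    if k <= 0:
        raise ValueError("k must be positive")
    return intensity > background_mean + k * background_sd


def call_cell_code(
    record,
    k: float = DEFAULT_K,
    nuclear_ratio_min: float = DEFAULT_NUCLEAR_RATIO_MIN,
) -> tuple[ColorCode, list[str]]:
    """Call the 12-entry color code of one cell.

    ``record`` is a mapping (e.g. a DataFrame row) with keys
    ``"<XFP>_nuc"``, ``"<XFP>_cyt"``, ``"bg_mean_<XFP>"`` and
    ``"bg_sd_<XFP>"`` for each of the six channels.

    Per channel: the cytoplasm entry is positive iff its measurement passes
    the background test.  The nucleus entry is positive iff its measurement
    passes AND either the nucleus/cytoplasm ratio is at least
    ``nuclear_ratio_min`` or the cytoplasm itself is negative (pure nuclear
    signal).  Both entries may be positive: the two targeted constructs are
    independent.

    Returns the code plus the names of channels whose nuclear measurement
    passed the background test but was vetoed by the ratio rule — ambiguous
    calls, flagged rather than silently dropped.
    """
    nuc_bits = []
    cyt_bits = []
    ambiguous: list[str] = []
    for name in CHANNEL_NAMES:
        for key in (f"{name}_nuc", f"{name}_cyt",
                    f"bg_mean_{name}", f"bg_sd_{name}"):
            if key not in record or pd.isna(record[key]):
                raise KeyError(f"missing measurement {key!r} for channel {name}")
        bg_mean = float(record[f"bg_mean_{name}"])
        bg_sd = float(record[f"bg_sd_{name}"])
        nuc = float(record[f"{name}_nuc"])
        cyt = float(record[f"{name}_cyt"])
        cyt_pos = call_presence(cyt, bg_mean, bg_sd, k)
        nuc_raw = call_presence(nuc, bg_mean, bg_sd, k)
        ratio = nuc / cyt if cyt > 0 else float("inf")
        nuc_pos = nuc_raw and (ratio >= nuclear_ratio_min or not cyt_pos)
        if nuc_raw and not nuc_pos:
            ambiguous.append(name)
        nuc_bits.append(nuc_pos)
        cyt_bits.append(cyt_pos)
    return ColorCode(tuple(nuc_bits), tuple(cyt_bits)), ambiguous


@dataclass
class CallingResult:
    """Cell table with codes filled in, plus exclusion bookkeeping."""

    cells: pd.DataFrame          # all input cells, ``code`` column populated
    labeled: pd.DataFrame        # the subset with nonempty codes
    n_excluded: int              # cells with empty called codes
    ambiguous: dict[str, list[str]]  # cell_id -> vetoed nuclear channels


def call_table(
    cells: pd.DataFrame,
    k: float = DEFAULT_K,
    nuclear_ratio_min: float = DEFAULT_NUCLEAR_RATIO_MIN,
) -> CallingResult:
    """Call a code for every row of a cell table.

    Calling is strictly per-cell, so permuting the input rows permutes the
    output identically.
    """
    codes = []
    ambiguous: dict[str, list[str]] = {}
    for _, row in cells.iterrows():
        code, amb = call_cell_code(row, k=k, nuclear_ratio_min=nuclear_ratio_min)
        codes.append(serialize_code(code))
        if amb:
            ambiguous[str(row["cell_id"])] = amb
    out = cells.copy()
    out["code"] = codes
    labeled = filter_labeled(out)
    return CallingResult(
        cells=out, labeled=labeled,
        n_excluded=len(out) - len(labeled), ambiguous=ambiguous)


_EMPTY_CODE = serialize_code(ColorCode.empty())


def filter_labeled(cells: pd.DataFrame) -> pd.DataFrame:
    """Retain cells whose called code has at least one construct present."""
    return cells[cells["code"] != _EMPTY_CODE].reset_index(drop=True)


def expected_called_code(
    code: ColorCode,
    background_mean: float,
    signal_mean: float,
    background_sd: float = 0.0,
    k: float = DEFAULT_K,
    nuclear_ratio_min: float = DEFAULT_NUCLEAR_RATIO_MIN,
) -> ColorCode:
    """The code the noise-free calling rule returns for a true code.

    Clonal identity is observable only up to this map: with typical signal
    strengths a channel present in both compartments reads a
    nucleus/cytoplasm ratio near 1, so its nuclear entry is vetoed and the
    channel is called cytoplasm-only.  The synthetic generator uses this map
    to guarantee that distinct progenitors remain distinguishable after
    calling.
    """
    nuc_bits = []
    cyt_bits = []
    threshold = background_mean + k * background_sd
    for i in range(len(CHANNEL_NAMES)):
        nuc = background_mean + (signal_mean if code.nucleus[i] else 0.0)
        cyt = background_mean + (signal_mean if code.cytoplasm[i] else 0.0)
        cyt_pos = cyt > threshold
        ratio = nuc / cyt if cyt > 0 else float("inf")
        nuc_pos = (nuc > threshold) and (ratio >= nuclear_ratio_min
                                         or not cyt_pos)
        nuc_bits.append(nuc_pos)
        cyt_bits.append(cyt_pos)
    return ColorCode(tuple(nuc_bits), tuple(cyt_bits))
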