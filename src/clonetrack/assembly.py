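"""Clone assembly by shared color code, and code-collision risk.

Sibling cells are, by definition, cells within one embryo carrying the same
nonempty color code; grouping never crosses embryos.  The method's known
failure mode is a code collision — two independently targeted progenitors
drawing the same uptake pattern — which silently merges their clones.
:func:`collision_probability` quantifies that risk under the independent
Bernoulli-uptake model, where a nonempty code ``c`` occurs with probability
``q(c) = p^|c| (1-p)^(12-|c|) / (1 - (1-p)^12)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode import N_CONSTRUCTS, ColorCode, code_complexity, parse_code

__all__ = [
    "Clone",
    "assemble_clones",
    "clone_table",
    "collision_probability",
    "tangential_dispersion",
]


@dataclass
class Clone:
    """A set of sibling cells: one embryo, one shared color code."""

    embryo_id: str
    code: ColorCode
    cell_ids: list[str]
    member_layers: list[str] = field(default_factory=list)
    member_types: list[str] = field(default_factory=list)
    tangential_um: list[float] = field(default_factory=list)
    sections: set[int] = field(default_factory=set)
    low_confidence: bool = False
    layer_class: str | None = None
    potency_class: str | None = None

    @property
    def size(self) -> int:
        return len(self.cell_ids)

    @property
    def code_string(self) -> str:
        from .barcode import serialize_code
        return serialize_code(self.code)


def assemble_clones(
    labeled_cells: pd.DataFrame,
    min_complexity: int = 1,
) -> list[Clone]:
    """Partition labeled cells into clones keyed by (embryo, code).

    Requires every row to carry an ``embryo_id`` and a nonempty ``code``
    string.  Clones whose code complexity is below ``min_complexity`` are
    flagged low-confidence (single-construct codes are the likeliest to
    collide) but are never dropped.  Output is sorted by embryo, then by
    descending size, ties broken by the canonical code string.
    """
    if "embryo_id" not in labeled_cells.columns:
        raise ValueError("cell table lacks an embryo_id column")
    if labeled_cells["embryo_id"].isna().any():
        bad = labeled_cells.loc[labeled_cells["embryo_id"].isna(), "cell_id"]
        raise ValueError(f"cells without an embryo id: {list(bad)[:5]}")

    clones: dict[tuple[str, str], Clone] = {}
    for _, row in labeled_cells.iterrows():
        code = parse_code(row["code"])
        if code.is_empty:
            raise ValueError(
                f"cell {row['cell_id']} has an empty code; filter unlabeled "
                "cells before assembly")
        key = (str(row["embryo_id"]), row["code"])
        clone = clones.get(key)
        if clone is None:
            clone = Clone(embryo_id=key[0], code=code, cell_ids=[],
                          low_confidence=code_complexity(code) < min_complexity)
            clones[key] = clone
        clone.cell_ids.append(str(row["cell_id"]))
        if "layer" in row.index and pd.notna(row["layer"]):
            clone.member_layers.append(str(row["layer"]))
        if "cell_type" in row.index and isinstance(row["cell_type"], str) \
                and row["cell_type"]:
            clone.member_types.append(row["cell_type"])
        if "tangential_um" in row.index and pd.notna(row["tangential_um"]):
            clone.tangential_um.append(float(row["tangential_um"]))
        if "section_index" in row.index and pd.notna(row["section_index"]):
            clone.sections.add(int(row["section_index"]))

    return sorted(
        clones.values(),
        key=lambda c: (c.embryo_id, -c.size, c.code_string))


def tangential_dispersion(clone: Clone) -> tuple[float, int]:
    """Tangential span (max - min position, um) and distinct-section count."""
    if not clone.tangential_um:
        return 0.0, len(clone.sections)
    span = max(clone.tangential_um) - min(clone.tangential_um)
    return float(span), len(clone.sections) if clone.sections else 1


def clone_table(clones: list[Clone]) -> pd.DataFrame:
    """Flat summary table: one row per clone."""
    rows = []
    for c in clones:
        span, n_sections = tangential_dispersion(c)
        rows.append({
            "embryo_id": c.embryo_id,
            "code": c.code_string,
            "size": c.size,
            "complexity": code_complexity(c.code),
            "n_sections": n_sections,
            "tangential_span_um": span,
            "low_confidence": c.low_confidence,
            "layer_class": c.layer_class,
            "potency_class": c.potency_class,
        })
    return pd.DataFrame(rows, columns=[
        "embryo_id", "code", "size", "complexity", "n_sections",
        "tangential_span_um", "low_confidence", "layer_class",
        "potency_class"])


# ---------------------------------------------------------------------------
# collision risk


def _complexity_power_sums(p_uptake: float) -> tuple[float, float]:
    """Power sums S2 = sum_c q(c)^2 and S3 = sum_c q(c)^3 over nonempty codes.

    Codes of equal complexity are equiprobable, so the sums collapse to 12
    binomial terms — the exact closed form of a dynamic program over
    complexity classes.
    """
    m = N_CONSTRUCTS
    norm = 1.0 - (1.0 - p_uptake) ** m
    s2 = s3 = 0.0
    for kk in range(1, m + 1):
        q = p_uptake**kk * (1.0 - p_uptake) ** (m - kk) / norm
        n_codes = math.comb(m, kk)
        s2 += n_codes * q * q
        s3 += n_codes * q * q * q
    return s2, s3


def collision_probability(
    n_progenitors: int,
    p_uptake: float,
    method: str = "auto",
    n_draws: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Probability that >= 2 of n labeled progenitors share a color code.

    Codes are nonuniform (complexity-k codes have probability
    ``p^k (1-p)^(12-k)``, conditioned on nonemptiness), so this is a
    birthday problem over 4095 unequally likely cells.

    ``method="exact"`` (n <= 3) evaluates the closed form via power sums of
    the code distribution; ``method="monte-carlo"`` simulates ``n_draws``
    cohorts of n conditioned-nonempty uptake draws.  ``"auto"`` picks exact
    when available.  Returns ``(probability, standard_error)``; the SE is 0
    for exact results.
    """
    if n_progenitors < 1:
        raise ValueError("n_progenitors must be >= 1")
    if p_uptake <= 0.0:
        raise ValueError(
            "p_uptake = 0 is degenerate: every code is empty and no clone "
            "is ever observed")
    if p_uptake >= 1.0:
        # only the all-present code exists
        return (0.0, 0.0) if n_progenitors == 1 else (1.0, 0.0)
    if n_progenitors == 1:
        return 0.0, 0.0

    if method == "auto":
        method = "exact" if n_progenitors <= 3 else "monte-carlo"

    if method == "exact":
        if n_progenitors > 3:
            raise ValueError("exact computation is implemented for n <= 3; "
                             "use method='monte-carlo'")
        s2, s3 = _complexity_power_sums(p_uptake)
        if n_progenitors == 2:
            return s2, 0.0
        # P(all 3 distinct) = 1 - 3*S2 + 2*S3 (distinct ordered triples)
        return 3.0 * s2 - 2.0 * s3, 0.0

    if method != "monte-carlo":
        raise ValueError(f"unknown method {method!r}")

    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = n_progenitors
    hits = 0
    done = 0
    batch = max(1, min(n_draws, 200_000 // max(n, 1)))
    while done < n_draws:
        b = min(batch, n_draws - done)
        bits = rng.random((b, n, N_CONSTRUCTS)) < p_uptake
        # condition each draw on nonemptiness by resampling empty codes
        empty = ~bits.any(axis=2)
        while empty.any():
            idx = np.where(empty)
            bits[idx] = rng.random((len(idx[0]), N_CONSTRUCTS)) < p_uptake
            empty = ~bits.any(axis=2)
        # pack 12 bits into ints, then look for duplicates within each cohort
        packed = (bits * (1 << np.arange(N_CONSTRUCTS))).sum(axis=2)
        packed.sort(axis=1)
        dup = (np.diff(packed, axis=1) == 0).any(axis=1)
        hits += int(dup.sum())
        done += b
    p_hat = hits / n_draws
    se = math.sqrt(p_hat * (1.0 - p_hat) / n_draws)
    return p_hat, se
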