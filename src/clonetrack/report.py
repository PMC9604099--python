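"""Cohort summary statistics and the two bespoke curve analyses.

Covers every aggregate the clonal analysis reports: per-layer labeled-cell
percentages, the seven clone layer-class proportions with per-class cell
totals and mean clone size +/- SEM, progenitor-potency proportions, the
fraction of clones containing ganglion cells, the per-embryo cells~clones
correlation, a locally-weighted polynomial regression of clone-size counts
(with pointwise standard errors), and kernel density estimates of clone size
by potency class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assembly import Clone
from .classify import LAYER_CLASSES, LAYERS

__all__ = [
    "layer_percentages",
    "layer_percentages_from_counts",
    "mean_size_from_totals",
    "clone_class_stats",
    "potency_stats",
    "potency_stats_from_counts",
    "rgc_containing_fraction",
    "cells_clones_correlation",
    "LocalPolynomialRegression",
    "CurveFit",
    "size_count_fit",
    "size_density_by_potency",
    "CohortSummary",
    "summarize_cohort",
]


# ---------------------------------------------------------------------------
# layer shares


def layer_percentages_from_counts(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentage of labeled cells per nuclear layer, to 2 decimals."""
    total = sum(counts.get(l, 0) for l in LAYERS)
    if total <= 0:
        raise ValueError("no labeled cells: cannot compute layer percentages")
    return {l: round(100.0 * counts.get(l, 0) / total, 2) for l in LAYERS}


def layer_percentages(cells: pd.DataFrame) -> dict:
    """Pooled and per-embryo layer percentages of a labeled-cell table.

    Returns ``{"pooled": {...}, "per_embryo": {embryo: {...}}, "range":
    {layer: (min, max)}}`` with percentages at 2 decimals.
    """
    if len(cells) == 0:
        raise ValueError("no labeled cells: cannot compute layer percentages")
    pooled = layer_percentages_from_counts(cells["layer"].value_counts().to_dict())
    per_embryo = {
        str(eid): layer_percentages_from_counts(g["layer"].value_counts().to_dict())
        for eid, g in cells.groupby("embryo_id")
    }
    rng = {
        l: (min(v[l] for v in per_embryo.values()),
            max(v[l] for v in per_embryo.values()))
        for l in LAYERS
    } if per_embryo else {}
    return {"pooled": pooled, "per_embryo": per_embryo, "range": rng}


# ---------------------------------------------------------------------------
# clone classes


def mean_size_from_totals(n_cells: int, n_clones: int) -> float:
    """Mean clone size implied by a class's cell total and clone count (1 dp)."""
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    return round(n_cells / n_clones, 1)


def _mean_sem(sizes: Sequence[int]) -> tuple[float, float]:
    arr = np.asarray(sizes, dtype=float)
    mean = float(arr.mean())
    if len(arr) < 2:
        return mean, 0.0
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr)))
    return mean, sem


def clone_class_stats(clones: Sequence[Clone]) -> pd.DataFrame:
    """Per layer-class: clone count, proportion, cell total, size mean +/- SEM.

    Proportions are percentages of all clones (2 dp); mean and SEM are
    reported to 1 dp, with the single-clone SEM taken as 0 by convention.
    Classes with no clones get proportion 0 and absent (NaN) mean/SEM.
    """
    if not clones:
        raise ValueError("no clones to summarise")
    total = len(clones)
    rows = []
    for cls in LAYER_CLASSES:
        members = [c for c in clones if c.layer_class == cls]
        sizes = [c.size for c in members]
        if members:
            mean, sem = _mean_sem(sizes)
            rows.append({
                "layer_class": cls, "n_clones": len(members),
                "proportion_pct": round(100.0 * len(members) / total, 2),
                "n_cells": int(sum(sizes)),
                "mean_size": round(mean, 1), "sem_size": round(sem, 1)})
        else:
            rows.append({
                "layer_class": cls, "n_clones": 0, "proportion_pct": 0.0,
                "n_cells": 0, "mean_size": float("nan"),
                "sem_size": float("nan")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# potency


def potency_stats_from_counts(
    n_multipotent: int, n_bipotent: int, n_committed: int, n_undetermined: int
) -> dict[str, float]:
    """Potency proportions (percent, 2 dp) from class counts.

    Reports the undetermined share of all clones, the determined share, the
    bi/multipotent share *of determined clones*, and the committed share of
    all clones — the four figures the analysis quotes.
    """
    total = n_multipotent + n_bipotent + n_committed + n_undetermined
    if total <= 0:
        raise ValueError("no clones to summarise")
    determined = n_multipotent + n_bipotent + n_committed
    out = {
        "undetermined_pct": round(100.0 * n_undetermined / total, 2),
        "determined_pct": round(100.0 * determined / total, 2),
        "committed_pct": round(100.0 * n_committed / total, 2),
    }
    out["bi_multipotent_of_determined_pct"] = (
        round(100.0 * (n_multipotent + n_bipotent) / determined, 2)
        if determined else float("nan"))
    return out


def potency_stats(clones: Sequence[Clone]) -> dict[str, float]:
    if not clones:
        raise ValueError("no clones to summarise")
    counts = {"multipotent": 0, "bipotent": 0, "committed": 0,
              "undetermined": 0}
    for c in clones:
        if c.potency_class not in counts:
            raise ValueError(f"clone lacks a potency class: {c.code_string}")
        counts[c.potency_class] += 1
    return potency_stats_from_counts(
        counts["multipotent"], counts["bipotent"], counts["committed"],
        counts["undetermined"])


def rgc_containing_fraction(clones: Sequence[Clone]) -> dict:
    """Fraction of clones containing >= 1 ganglion cell, pooled and per embryo.

    Both complementary percentages are reported (with vs without RGCs).
    """
    def pct(members: Sequence[Clone]) -> float:
        if not members:
            return float("nan")
        n = sum(1 for c in members if "RGC" in c.member_types)
        return round(100.0 * n / len(members), 2)

    pooled = pct(clones)
    per_embryo = {}
    for eid in sorted({c.embryo_id for c in clones}):
        per_embryo[eid] = pct([c for c in clones if c.embryo_id == eid])
    return {
        "with_rgc_pct": pooled,
        "without_rgc_pct": round(100.0 - pooled, 2),
        "per_embryo_with_rgc_pct": per_embryo,
    }


def cells_clones_correlation(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson correlation of per-embryo (labeled cells, clones) pairs."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 embryos to correlate")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# locally-weighted polynomial regression of clone-size counts


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


@dataclass
class CurveFit:
    """A fitted local-polynomial curve with pointwise uncertainty.

    ``fitted[i]`` and ``se[i]`` refer to ``grid[i]``; the 95% band is
    ``fitted +/- 1.96 * se``.  ``mean_se_up_to[s]`` is the average pointwise
    SE over grid points <= s, quantifying how well the fit tracks the data
    over the small-clone range.
    """

    grid: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    span: float
    degree: int
    residual_scale: float
    mean_se_up_to: dict[int, float] = field(default_factory=dict)

    @property
    def band_low(self) -> np.ndarray:
        return self.fitted - 1.96 * self.se

    @property
    def band_high(self) -> np.ndarray:
        return self.fitted + 1.96 * self.se


class LocalPolynomialRegression:
    """Locally-weighted polynomial regression (LOESS) from first principles.

    At each evaluation point the ``span`` fraction of nearest data points is
    weighted by the tricube kernel and a degree-``degree`` polynomial is fit
    by weighted least squares; the fitted value and its standard error come
    from the closed-form linear-smoother row, with the residual scale
    estimated globally from the smoother's effective degrees of freedom.
    """

    def __init__(self, x, y, span: float = 0.75, degree: int = 2):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be equal-length 1-d arrays")
        if not 0.0 < span <= 1.0:
            raise ValueError("span must lie in (0, 1]")
        if degree < 0:
            raise ValueError("degree must be >= 0")
        if len(np.unique(self.x)) < degree + 2:
            raise ValueError(
                f"need at least degree + 2 = {degree + 2} distinct x values")
        self.span = float(span)
        self.degree = int(degree)

    def _weights_at(self, x0: float) -> np.ndarray:
        """Tricube weights over the span-fraction nearest neighbours of x0."""
        d = np.abs(self.x - x0)
        n = len(self.x)
        q = max(int(math.ceil(self.span * n)), self.degree + 2)
        q = min(q, n)
        while True:
            h = np.sort(d)[q - 1]
            if h == 0:
                h = np.finfo(float).tiny
            w = _tricube(d / h)
            if (w > 0).sum() >= self.degree + 1 or q == n:
                break
            warnings.warn(
                f"local window at x={x0:g} has fewer points than parameters; "
                "widening", stacklevel=2)
            q += 1
        if (w > 0).sum() < self.degree + 1:
            # all mass on one x: fall back to uniform weights
            w = np.ones(n)
        return w

    def _smoother_row(self, x0: float) -> np.ndarray:
        """Row r with fitted(x0) = r @ y (the linear-smoother form)."""
        w = self._weights_at(x0)
        dx = self.x - x0
        X = np.vander(dx, N=self.degree + 1, increasing=True)
        XtW = X.T * w
        beta_map = np.linalg.pinv(XtW @ X) @ XtW
        return beta_map[0]  # fitted value at x0 is the centered intercept

    def fit(self, grid=None) -> CurveFit:
        x, y = self.x, self.y
        if grid is None:
            grid = np.unique(x)
        grid = np.sort(np.asarray(grid, dtype=float))
        rows = np.vstack([self._smoother_row(g) for g in grid])
        fitted = rows @ y

        # residual scale from the smoother evaluated at the data points
        L = np.vstack([self._smoother_row(xi) for xi in x])
        resid = y - L @ y
        df = max(len(x) - np.trace(L), 1.0)
        sigma = float(math.sqrt(float(resid @ resid) / df))

        se = sigma * np.sqrt((rows**2).sum(axis=1))
        mean_se_up_to = {
            int(s): float(se[grid <= s].mean())
            for s in np.unique(grid.astype(int)) if (grid <= s).any()
        }
        return CurveFit(grid=grid, fitted=fitted, se=se, span=self.span,
                        degree=self.degree, residual_scale=sigma,
                        mean_se_up_to=mean_se_up_to)


def size_count_fit(
    clone_sizes: Sequence[int],
    span: float = 0.75,
    degree: int = 2,
    grid=None,
) -> CurveFit:
    """Fit clone-size counts (number of clones of each size) by LOESS.

    Builds the (size, count) scatter over the observed distinct sizes and
    smooths it with a locally-weighted polynomial; the returned
    ``mean_se_up_to`` profile shows over which size range the regression is
    best supported.
    """
    sizes = np.asarray(clone_sizes, dtype=int)
    if sizes.size == 0:
        raise ValueError("no clone sizes supplied")
    uniq, counts = np.unique(sizes, return_counts=True)
    model = LocalPolynomialRegression(uniq.astype(float),
                                      counts.astype(float),
                                      span=span, degree=degree)
    return model.fit(grid=grid)


# ---------------------------------------------------------------------------
# size densities by potency


def size_density_by_potency(
    clones: Sequence[Clone],
    grid=None,
    merge_bi_multipotent: bool = True,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Gaussian KDE of clone size per potency class (Silverman bandwidth).

    Bipotent and multipotent clones are pooled into one "bi_multipotent"
    curve by default, mirroring how mixed clones are usually displayed.
    Classes with fewer than two clones are omitted with a warning.  Each
    returned ``(grid, density)`` integrates to ~1 over its grid.
    """
    groups: dict[str, list[int]] = {}
    for c in clones:
        key = c.potency_class or "unclassified"
        if merge_bi_multipotent and key in ("bipotent", "multipotent"):
            key = "bi_multipotent"
        groups.setdefault(key, []).append(c.size)

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for key, sizes in sorted(groups.items()):
        if len(sizes) < 2 or len(set(sizes)) < 2:
            warnings.warn(
                f"potency class {key!r} has too few clones for a density; "
                "omitted", stacklevel=2)
            continue
        arr = np.asarray(sizes, dtype=float)
        kde = sps.gaussian_kde(arr, bw_method="silverman")
        if grid is None:
            # wide enough that the density's mass is captured: the kernel
            # reaches ~5 bandwidths beyond the extreme observations
            bw = float(np.sqrt(kde.covariance[0, 0]))
            lo = arr.min() - 5 * bw
            hi = arr.max() + 5 * bw
            g = np.linspace(lo, hi, 512)
        else:
            g = np.asarray(grid, dtype=float)
        out[key] = (g, kde(g))
    return out


# ---------------------------------------------------------------------------
# full summary


@dataclass
class CohortSummary:
    """Every aggregate the analysis reports, ready for JSON."""

    n_cells_analyzed: int
    n_cells_assigned: int
    n_clones: int
    layer: dict
    clone_classes: list[dict]
    potency: dict[str, float]
    rgc: dict
    per_embryo_cells_clones: list[dict]
    cells_clones_r: float | None
    size_fit: dict | None

    def to_dict(self) -> dict:
        return {
            "n_cells_analyzed": self.n_cells_analyzed,
            "n_cells_assigned": self.n_cells_assigned,
            "n_clones": self.n_clones,
            "layer_percentages": self.layer,
            "clone_classes": self.clone_classes,
            "potency": self.potency,
            "rgc": self.rgc,
            "per_embryo_cells_clones": self.per_embryo_cells_clones,
            "cells_clones_pearson_r": self.cells_clones_r,
            "size_count_fit": self.size_fit,
        }


def summarize_cohort(
    labeled_cells: pd.DataFrame,
    clones: Sequence[Clone],
    n_cells_analyzed: int | None = None,
    span: float = 0.75,
    degree: int = 2,
) -> CohortSummary:
    """Assemble the full cohort summary from classified cells and clones."""
    layer = layer_percentages(labeled_cells)
    classes = clone_class_stats(clones).to_dict(orient="records")
    potency = potency_stats(clones)
    rgc = rgc_containing_fraction(clones)

    per_embryo = []
    pairs = []
    for eid, g in labeled_cells.groupby("embryo_id"):
        n_clones_e = sum(1 for c in clones if c.embryo_id == str(eid))
        per_embryo.append({"embryo_id": str(eid), "n_cells": int(len(g)),
                           "n_clones": n_clones_e})
        pairs.append((len(g), n_clones_e))
    try:
        r = cells_clones_correlation(pairs)
    except ValueError:
        r = None

    sizes = [c.size for c in clones]
    size_fit = None
    if len(set(sizes)) >= degree + 2:
        fit = size_count_fit(sizes, span=span, degree=degree)
        size_fit = {
            "grid": fit.grid.tolist(),
            "fitted": fit.fitted.tolist(),
            "se": fit.se.tolist(),
            "span": fit.span,
            "degree": fit.degree,
            "mean_se_up_to": {str(k): v for k, v in fit.mean_se_up_to.items()},
        }

    return CohortSummary(
        n_cells_analyzed=(n_cells_analyzed if n_cells_analyzed is not None
                          else len(labeled_cells)),
        n_cells_assigned=len(labeled_cells),
        n_clones=len(clones),
        layer=layer, clone_classes=classes, potency=potency, rgc=rgc,
        per_embryo_cells_clones=per_embryo, cells_clones_r=r,
        size_fit=size_fit)
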