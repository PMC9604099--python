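"""Optional figures: size-count fit, clone-class pie, size densities."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .assembly import Clone
from .report import CurveFit, clone_class_stats, size_density_by_potency

__all__ = ["plot_size_count_fit", "plot_clone_class_pie",
           "plot_size_densities"]


def plot_size_count_fit(fit: CurveFit, sizes: Sequence[int], path) -> Path:
    """Clone-size count scatter with the local-polynomial fit and 95% band."""
    import numpy as np
    uniq, counts = np.unique(np.asarray(sizes, dtype=int),
                             return_counts=True)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(uniq, counts, s=18, color="k", zorder=3, label="counts")
    ax.plot(fit.grid, fit.fitted, color="tab:blue", label="local fit")
    ax.fill_between(fit.grid, fit.band_low, fit.band_high,
                    color="grey", alpha=0.35, label="95% band")
    ax.set_xlabel("clone size (cells)")
    ax.set_ylabel("number of clones")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_clone_class_pie(clones: Sequence[Clone], path) -> Path:
    """Pie of the seven clone layer-distribution classes."""
    stats = clone_class_stats(list(clones))
    stats = stats[stats["n_clones"] > 0]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.pie(stats["n_clones"], labels=stats["layer_class"],
           autopct="%1.1f%%", startangle=90, counterclock=False)
    ax.set_title("clone layer distribution")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_size_densities(clones: Sequence[Clone], path) -> Path:
    """Clone-size density per potency class (Gaussian KDE)."""
    curves = size_density_by_potency(list(clones))
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, (grid, density) in curves.items():
        ax.plot(grid, density, label=label)
        ax.fill_between(grid, density, alpha=0.2)
    ax.set_xlabel("clone size (cells)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
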