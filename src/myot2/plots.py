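"""Diagnostic figures: T2 histogram with Gaussian overlay, Bland-Altman,
metric-vs-dye regression scatter and the skew-vs-IDR stratification plane."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .cohort import RegressionResult, RepeatabilityResult
from .metrics import T2Distribution

__all__ = [
    "histogram_with_gaussian",
    "bland_altman_plot",
    "dye_regression_plot",
    "stratification_plot",
]


def histogram_with_gaussian(dist: T2Distribution, path: str | Path) -> Path:
    """Histogram of trimmed muscle T2 values with the (mean, sd) Gaussian
    overplotted — the visual argument that mean/sd misdescribe the data."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    v = dist.values_ms
    ax.hist(v, bins=60, density=True, color="#4878b0", alpha=0.85)
    if dist.sd_ms > 0:
        x = np.linspace(v.min(), v.max(), 400)
        ax.plot(x, stats.norm.pdf(x, dist.mean_ms, dist.sd_ms), "r--",
                label=f"N({dist.mean_ms:.1f}, {dist.sd_ms:.1f}²)")
        ax.legend(frameon=False)
    ax.axvline(dist.mode_ms, color="k", lw=0.8, ls=":")
    ax.set_xlabel("T2 (ms)")
    ax.set_ylabel("density")
    ax.set_title(f"IDR={dist.idr_ms:.2f} ms, skew={dist.pearson_skew:.3f}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def bland_altman_plot(pairs: np.ndarray, result: RepeatabilityResult,
                      path: str | Path, label: str = "metric") -> Path:
    pairs = np.asarray(pairs, dtype=float)
    means = pairs.mean(axis=1)
    diffs = pairs[:, 1] - pairs[:, 0]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(means, diffs, color="#333")
    for y, style in ((result.bias, "-"), (result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(y, color="r", ls=style, lw=0.9)
    ax.set_xlabel(f"mean {label}")
    ax.set_ylabel(f"session difference ({label})")
    ax.set_title(f"bias={result.bias:.3g}, MDC={result.mdc:.3g}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def dye_regression_plot(x: np.ndarray, dye: np.ndarray, result: RegressionResult,
                        path: str | Path, label: str = "IDR (ms)") -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(x, dye, color="#333")
    xs = np.linspace(min(x), max(x), 50)
    ax.plot(xs, result.intercept + result.slope * xs, "r-",
            label=f"R²={result.r_squared:.2f}")
    ax.set_xlabel(label)
    ax.set_ylabel("dye uptake (a.u./mg)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def stratification_plot(scatter, path: str | Path) -> Path:
    """Skew vs IDR, one marker per animal, colored by genotype."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for genotype, sub in scatter.groupby("genotype"):
        ax.scatter(sub["idr_ms"], sub["pearson_skew"], label=genotype, s=30)
    ax.set_xlabel("IDR (ms)")
    ax.set_ylabel("Pearson skew")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
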