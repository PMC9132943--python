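"""Optional PNG figures (requires matplotlib).

Thin helpers for the three standard views: recovery curve with its
exponential fit, dual-channel intensity scatter, and the folded
axial-position histogram of first assembly events.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .coloc import ColocResult
from .frap import FrapCurve, FrapEstimate


def _pyplot():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_recovery(curve: FrapCurve, estimate: FrapEstimate,
                  path: str | Path) -> None:
    """Recovery curve with the fitted exponential overlay."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.times / 60, curve.values, "o", ms=3, label="observed")
    if np.isfinite(estimate.tau):
        t = np.linspace(0, curve.times[-1], 200)
        fit = curve.values[0] + estimate.A * (1 - np.exp(-estimate.tau * t))
        ax.plot(t / 60, fit, "-", label=(
            f"fit: M={estimate.M:.2f}, "
            f"$\\tau_{{1/2}}$={estimate.half_time:.0f} s"))
    ax.set_xlabel("time after bleach (min)")
    ax.set_ylabel("normalized fluorescence")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter(result: ColocResult, path: str | Path,
                 labels: tuple[str, str] = ("channel 1", "channel 2")) -> None:
    """Paired-pixel intensity scatter annotated with Pearson R."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(result.scatter[:, 0], result.scatter[:, 1], ".", ms=1, alpha=0.4)
    ax.set_xlabel(f"{labels[0]} intensity")
    ax.set_ylabel(f"{labels[1]} intensity")
    ax.set_title(f"Pearson R = {result.pearson_r:.2f} "
                 f"(n = {result.n_pixels} px)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_position_histogram(folded_positions: Sequence[float],
                            path: str | Path) -> None:
    """Histogram of folded axial positions, 0.05-wide bins over [0, 0.5]."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(folded_positions, bins=np.arange(0, 0.5001, 0.05),
            edgecolor="black")
    ax.set_xlabel("folded axial position (0 = pole, 0.5 = mid-cell)")
    ax.set_ylabel("events")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
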