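"""Matplotlib helpers for the simulation envelope and chromatograms."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")  # headless default; callers may switch backends first
import matplotlib.pyplot as plt

from .pk import SimulationSummary
from .synth import Chromatogram

__all__ = ["plot_concentration_envelope", "plot_chromatogram"]


def plot_concentration_envelope(
    summaries: Mapping[str, SimulationSummary], ax: plt.Axes | None = None
) -> plt.Axes:
    """Shaded percentile band per route over the simulated horizon."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for route, summary in summaries.items():
        ax.fill_between(summary.times, summary.lower, summary.upper, alpha=0.3, label=route)
        if summary.median is not None:
            ax.plot(summary.times, summary.median, lw=1)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ug/mL)")
    ax.set_yscale("log")
    ax.legend(title="route")
    return ax


def plot_chromatogram(chromatogram: Chromatogram, ax: plt.Axes | None = None) -> plt.Axes:
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(chromatogram.times, chromatogram.intensities, lw=0.8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("fluorescence (a.u.)")
    ax.set_title(chromatogram.sample_id)
    return ax
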