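"""Peak detection, baseline-noise estimation, signal-to-noise and limit decisions.

Quantification is by baseline-corrected peak height (not area): the analyte and
IS peaks are located inside retention-time windows, their heights measured
above a baseline level estimated from a signal-free region, and the
signal-to-noise ratio (S/N) computed as height divided by the baseline noise
SD. Detection and quantification limits follow the usual bioanalytical
convention: the LLOD is the lowest level with S/N > 3; the LLOQ additionally
requires S/N > 10 and acceptable accuracy (80-120%) and precision (<20%) at
that level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import InvalidInputError, InvalidRegionError
from .synth import Chromatogram

__all__ = [
    "Peak",
    "RetentionWindow",
    "LimitDecision",
    "estimate_baseline",
    "detect_peak",
    "signal_to_noise",
    "determine_lloq_llod",
]

MIN_BASELINE_SAMPLES = 20


@dataclass(frozen=True)
class RetentionWindow:
    """Expected retention time and a symmetric search tolerance, minutes."""

    expected_rt: float
    tolerance: float = 0.2

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise InvalidInputError("tolerance must be positive")

    @property
    def bounds(self) -> tuple[float, float]:
        return self.expected_rt - self.tolerance, self.expected_rt + self.tolerance


@dataclass(frozen=True)
class Peak:
    """A detected chromatographic peak (height above baseline)."""

    retention_time: float
    height: float
    area: float
    s_n: float


def estimate_baseline(
    chromatogram: Chromatogram,
    signal_free_region: tuple[float, float] = (1.0, 5.0),
    peak_windows: Sequence[RetentionWindow] = (),
) -> tuple[float, float]:
    """(baseline level, noise SD) from a signal-free region of the trace.

    The level is the median intensity in the region, the noise the SD of the
    intensity there. The region must hold at least ``MIN_BASELINE_SAMPLES``
    points and must not overlap any configured peak window.
    """
    lo, hi = signal_free_region
    if hi <= lo:
        raise InvalidRegionError("region end must exceed region start")
    for window in peak_windows:
        wlo, whi = window.bounds
        if lo < whi and wlo < hi:
            raise InvalidRegionError(
                f"baseline region ({lo}, {hi}) overlaps peak window around {window.expected_rt}"
            )
    mask = (chromatogram.times >= lo) & (chromatogram.times <= hi)
    if mask.sum() < MIN_BASELINE_SAMPLES:
        raise InvalidRegionError(
            f"baseline region holds {int(mask.sum())} samples; need >= {MIN_BASELINE_SAMPLES}"
        )
    values = chromatogram.intensities[mask]
    return float(np.median(values)), float(values.std(ddof=1))


def signal_to_noise(height: float, noise_sd: float) -> float:
    """Baseline-corrected height over baseline noise SD; inf for zero noise."""
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    if height <= 0:
        return 0.0
    if noise_sd == 0:
        return float("inf")
    return height / noise_sd


def _smooth(y: np.ndarray, width: int | None) -> np.ndarray:
    if not width or width <= 1:
        return y
    if width % 2 == 0:
        raise InvalidInputError("smoothing width must be odd")
    kernel = np.ones(width) / width
    return np.convolve(y, kernel, mode="same")


def detect_peak(
    chromatogram: Chromatogram,
    window: RetentionWindow,
    baseline_level: float,
    noise_sd: float,
    smoothing_width: int | None = None,
) -> Peak | None:
    """Highest qualifying local maximum inside the retention window, or None.

    A candidate qualifies when its baseline-corrected height exceeds
    3 x noise_sd (or simply exceeds zero for a noiseless trace). Exact height
    ties are broken toward the candidate nearest ``expected_rt``, then toward
    the earlier retention time. Area is the trapezoidal integral of the
    baseline-corrected trace over the window (clipped at zero), computed but
    unused by height-based quantification.
    """
    t, y = chromatogram.times, _smooth(chromatogram.intensities, smoothing_width)
    lo, hi = window.bounds
    if lo < t[0] or hi > t[-1]:
        raise InvalidInputError("retention window must lie inside the run time")
    mask = (t >= lo) & (t <= hi)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        return None
    seg = y[idx]
    maxima, _ = find_peaks(seg)
    if maxima.size == 0:
        return None
    heights = seg[maxima] - baseline_level
    threshold = 3.0 * noise_sd if noise_sd > 0 else 0.0
    keep = heights > threshold
    if not keep.any():
        return None
    maxima, heights = maxima[keep], heights[keep]
    best = heights.max()
    # ties: nearest to the expected rt, then earliest
    tied = np.flatnonzero(heights == best)
    rts = t[idx[maxima[tied]]]
    order = np.lexsort((rts, np.abs(rts - window.expected_rt)))
    pick = tied[order[0]]
    corrected = np.clip(seg - baseline_level, 0.0, None)
    area = float(np.trapezoid(corrected, t[idx]))
    height = float(heights[pick])
    return Peak(
        retention_time=float(t[idx[maxima[pick]]]),
        height=height,
        area=area,
        s_n=signal_to_noise(height, noise_sd),
    )


@dataclass(frozen=True)
class LimitDecision:
    """LLOQ/LLOD outcome; either limit may be undetermined (None)."""

    lloq: float | None
    llod: float | None


def determine_lloq_llod(
    sn_by_level: Mapping[float, float],
    qc_stats: Mapping[float, tuple[float, float]] | None = None,
    llod_sn: float = 3.0,
    lloq_sn: float = 10.0,
    accuracy_limits: tuple[float, float] = (80.0, 120.0),
    precision_max: float = 20.0,
) -> LimitDecision:
    """Decide the detection and quantification limits from per-level S/N.

    ``sn_by_level`` maps each probed concentration to its (worst-case or mean)
    S/N. ``qc_stats`` maps candidate levels to (accuracy %, precision %); when
    supplied, a level only qualifies as LLOQ if its accuracy lies inside
    ``accuracy_limits`` and its precision is strictly below ``precision_max``.
    A level with S/N above the LLOQ threshold but no stats is skipped. Failure
    to qualify is reported as None, never raised.
    """
    if not sn_by_level:
        raise InvalidInputError("sn_by_level must not be empty")
    llod = None
    lloq = None
    for level in sorted(sn_by_level):
        sn = sn_by_level[level]
        if llod is None and sn > llod_sn:
            llod = level
        if lloq is None and sn > lloq_sn:
            if qc_stats is None:
                lloq = level
            elif level in qc_stats:
                acc, prec = qc_stats[level]
                if accuracy_limits[0] <= acc <= accuracy_limits[1] and prec < precision_max:
                    lloq = level
    return LimitDecision(lloq=lloq, llod=llod)
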