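"""Synthetic HPLC-fluorescence data generator.

Stands in for the instrument: renders chromatograms with Gaussian analyte and
internal-standard (IS) peaks on a noisy baseline, reproducing the statistical
structure a bioanalytical validation assumes — peak height proportional to
concentration, log-normal (proportional) replicate-to-replicate height error,
additive white baseline noise, and small retention-time jitter.

Defaults emulate a 15-min isocratic serum assay with the analyte eluting near
12.9 min and the IS near 8.8 min. Sample-preparation arithmetic (stock and
spiking dilutions) is included so nominal concentrations trace back to a
working-solution plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "AssayGeometry",
    "ResponseModel",
    "SamplePlan",
    "Chromatogram",
    "stock_concentration",
    "spike_plan",
    "render_chromatogram",
    "generate_validation_dataset",
    "interpolate_level_cvs",
    "simulate_ratio_series",
    "DEFAULT_CALIBRATION_LEVELS",
    "DEFAULT_QC_LEVELS",
    "TABLE_PRECISION_ANCHORS",
]

#: calibration levels used for the curve fit (ug/mL); the additional 0.01
#: preparation level is a detection-limit probe only, never fitted
DEFAULT_CALIBRATION_LEVELS: tuple[float, ...] = (0.025, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0)
DEFAULT_QC_LEVELS: tuple[float, ...] = (0.025, 0.1, 5.0, 10.0)

#: intra-assay RSD anchors (fraction) at the low/medium/high QC levels used to
#: interpolate a realistic proportional-error CV at any concentration
TABLE_PRECISION_ANCHORS: dict[float, float] = {0.1: 0.032, 5.0: 0.017, 10.0: 0.005}

Role = Literal[
    "blank", "zero", "double-blank", "calibrator", "qc",
    "recovery_extracted", "recovery_reference",
]
_NO_ANALYTE_ROLES = ("blank", "zero", "double-blank")


@dataclass(frozen=True)
class AssayGeometry:
    """Chromatographic geometry of the simulated separation.

    Times in minutes, intensities in arbitrary fluorescence units. The IS must
    elute before the analyte and both inside the run.
    """

    run_time: float = 15.0
    sampling_rate: float = 120.0  # points per minute
    analyte_rt: float = 12.9
    is_rt: float = 8.8
    analyte_peak_sigma: float = 0.05
    is_peak_sigma: float = 0.05
    baseline_level: float = 10.0
    baseline_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.is_rt < self.analyte_rt < self.run_time:
            raise InvalidParameterError("require 0 < is_rt < analyte_rt < run_time")
        if self.analyte_peak_sigma <= 0 or self.is_peak_sigma <= 0:
            raise InvalidParameterError("peak sigmas must be positive")
        if self.baseline_noise_sd < 0:
            raise InvalidParameterError("baseline noise SD must be non-negative")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling rate must be positive")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.run_time * self.sampling_rate)) + 1
        return np.linspace(0.0, self.run_time, n)


@dataclass(frozen=True)
class ResponseModel:
    """Detector response and its error structure.

    ``analyte_response_factor`` converts concentration (ug/mL) to noiseless
    peak height; the IS is added at a fixed amount so its noiseless height is a
    constant. ``proportional_cv`` is the replicate-to-replicate log-normal
    height CV (applied independently to analyte and IS, so ratio noise
    compounds). ``extraction_efficiency`` scales heights of protein-
    precipitated samples relative to pre-spiked reference standards;
    ``day_effect_sd`` adds an optional log-normal between-day response shift.
    """

    analyte_response_factor: float = 100.0
    is_response_height: float = 1000.0
    proportional_cv: float = 0.005
    rt_jitter_sd: float = 0.007
    extraction_efficiency: float = 1.0
    day_effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.analyte_response_factor <= 0 or self.is_response_height <= 0:
            raise InvalidParameterError("response factors must be positive")
        if self.proportional_cv < 0 or self.rt_jitter_sd < 0 or self.day_effect_sd < 0:
            raise InvalidParameterError("noise magnitudes must be non-negative")
        if self.extraction_efficiency <= 0:
            raise InvalidParameterError("extraction efficiency must be positive")


@dataclass(frozen=True)
class SamplePlan:
    """One planned injection: its role, nominal concentration and position."""

    sample_id: str
    role: Role
    nominal_conc: float = 0.0
    day: int = 1
    replicate: int = 1
    with_is: bool = True
    prep: Literal["extracted", "reference"] = "extracted"

    def __post_init__(self) -> None:
        if self.role in _NO_ANALYTE_ROLES and self.nominal_conc != 0:
            raise InvalidParameterError(f"{self.role} samples must have nominal_conc 0")
        if self.nominal_conc < 0:
            raise InvalidParameterError("nominal_conc must be non-negative")


@dataclass(frozen=True)
class Chromatogram:
    """A uniformly sampled fluorescence trace."""

    times: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "intensity": self.intensities})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_id: str = "") -> "Chromatogram":
        return cls(
            times=frame["time_min"].to_numpy(dtype=float),
            intensities=frame["intensity"].to_numpy(dtype=float),
            sample_id=sample_id,
        )


def stock_concentration(mass_mg: float, final_volume_ml: float) -> float:
    """Concentration (ug/mL) of a stock made from ``mass_mg`` in ``final_volume_ml``."""
    if mass_mg <= 0 or final_volume_ml <= 0:
        raise InvalidInputError("mass and volume must be positive")
    return mass_mg * 1000.0 / final_volume_ml


def spike_plan(
    final_concs: Iterable[float], spike_volume_ul: float = 20.0, serum_volume_ul: float = 80.0
) -> list[float]:
    """Working-solution concentrations needed to reach each final serum level.

    Spiking ``spike_volume_ul`` of working solution into ``serum_volume_ul`` of
    blank serum dilutes it by (spike+serum)/spike, so the working solution must
    be that factor more concentrated than the final sample.
    """
    if spike_volume_ul <= 0 or serum_volume_ul < 0:
        raise InvalidInputError("spike volume must be positive; serum volume non-negative")
    factor = (spike_volume_ul + serum_volume_ul) / spike_volume_ul
    return [float(c) * factor for c in final_concs]


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 multiplicative log-normal error with the given CV."""
    if cv == 0:
        return 1.0
    sigma2 = np.log1p(cv**2)
    return float(rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2)))


def _realize(
    plan: SamplePlan,
    geometry: AssayGeometry,
    response: ResponseModel,
    rng: np.random.Generator,
    day_factor: float = 1.0,
) -> tuple[Chromatogram, dict]:
    """Render one chromatogram and return it with its realized ground truth."""
    t = geometry.time_grid()
    trace = np.full(t.shape, geometry.baseline_level, dtype=float)

    efficiency = response.extraction_efficiency if plan.prep == "extracted" else 1.0
    truth: dict = {
        "sample_id": plan.sample_id,
        "role": plan.role,
        "nominal_conc_ug_ml": plan.nominal_conc,
        "day": plan.day,
        "replicate": plan.replicate,
        "with_is": plan.with_is,
        "prep": plan.prep,
        "analyte_height": 0.0,
        "analyte_rt_min": np.nan,
        "is_height": 0.0,
        "is_rt_min": np.nan,
    }

    if plan.role not in _NO_ANALYTE_ROLES and plan.nominal_conc > 0:
        height = (
            response.analyte_response_factor
            * plan.nominal_conc
            * day_factor
            * efficiency
            * _lognormal_multiplier(rng, response.proportional_cv)
        )
        rt = geometry.analyte_rt + rng.normal(0.0, response.rt_jitter_sd)
        trace += height * np.exp(-((t - rt) ** 2) / (2.0 * geometry.analyte_peak_sigma**2))
        truth["analyte_height"] = height
        truth["analyte_rt_min"] = rt

    if plan.with_is:
        height = (
            response.is_response_height
            * day_factor
            * efficiency
            * _lognormal_multiplier(rng, response.proportional_cv)
        )
        rt = geometry.is_rt + rng.normal(0.0, response.rt_jitter_sd)
        trace += height * np.exp(-((t - rt) ** 2) / (2.0 * geometry.is_peak_sigma**2))
        truth["is_height"] = height
        truth["is_rt_min"] = rt

    if geometry.baseline_noise_sd > 0:
        trace += rng.normal(0.0, geometry.baseline_noise_sd, size=t.shape)

    return Chromatogram(times=t, intensities=trace, sample_id=plan.sample_id), truth


def render_chromatogram(
    plan: SamplePlan,
    geometry: AssayGeometry,
    response: ResponseModel,
    seed: int | np.random.Generator,
) -> Chromatogram:
    """Render a single chromatogram for a planned sample."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom, _ = _realize(plan, geometry, response, rng)
    return chrom


def generate_validation_dataset(
    levels: Sequence[float] = DEFAULT_CALIBRATION_LEVELS,
    qc_levels: Sequence[float] = DEFAULT_QC_LEVELS,
    replicates_per_day: int = 3,
    days: int = 3,
    geometry: AssayGeometry = AssayGeometry(),
    response: ResponseModel = ResponseModel(),
    seed: int | np.random.Generator = 0,
    llod_probe: float | None = 0.01,
    recovery_levels: Sequence[float] | None = None,
    n_blanks_per_day: int = 1,
) -> tuple[list[Chromatogram], pd.DataFrame]:
    """Render the full validation campaign and its ground-truth manifest.

    Per day: one calibrator per level, an optional detection-limit probe,
    blank/zero/double-blank injections, ``replicates_per_day`` QC replicates
    per QC level, and matched extracted/reference recovery pairs at the
    recovery levels (defaults to the QC levels above the LLOQ). Returns the
    chromatograms and a manifest recording every sample's nominal
    concentration and realized peak heights/retention times.
    """
    if replicates_per_day < 1 or days < 1:
        raise InvalidInputError("replicates_per_day and days must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if recovery_levels is None:
        recovery_levels = [c for c in qc_levels if c != min(qc_levels)]

    plans: list[SamplePlan] = []
    for day in range(1, days + 1):
        for b in range(1, n_blanks_per_day + 1):
            plans.append(SamplePlan(f"d{day}_blank{b}", "blank", 0.0, day, b, with_is=False))
            plans.append(SamplePlan(f"d{day}_zero{b}", "zero", 0.0, day, b, with_is=True))
        if llod_probe is not None:
            plans.append(SamplePlan(f"d{day}_llod", "calibrator", llod_probe, day, 1))
        for level in levels:
            plans.append(SamplePlan(f"d{day}_cal_{level:g}", "calibrator", level, day, 1))
        for level in qc_levels:
            for rep in range(1, replicates_per_day + 1):
                plans.append(SamplePlan(f"d{day}_qc_{level:g}_r{rep}", "qc", level, day, rep))
        for level in recovery_levels:
            for rep in range(1, replicates_per_day + 1):
                plans.append(
                    SamplePlan(
                        f"d{day}_recx_{level:g}_r{rep}", "recovery_extracted",
                        level, day, rep, prep="extracted",
                    )
                )
                plans.append(
                    SamplePlan(
                        f"d{day}_recr_{level:g}_r{rep}", "recovery_reference",
                        level, day, rep, prep="reference",
                    )
                )

    day_factors = {
        day: _lognormal_multiplier(rng, response.day_effect_sd)
        for day in range(1, days + 1)
    }
    chromatograms: list[Chromatogram] = []
    truths: list[dict] = []
    for plan in plans:
        chrom, truth = _realize(plan, geometry, response, rng, day_factors[plan.day])
        chromatograms.append(chrom)
        truths.append(truth)
    return chromatograms, pd.DataFrame(truths)


def interpolate_level_cvs(
    levels: Sequence[float],
    anchors: Mapping[float, float] = TABLE_PRECISION_ANCHORS,
    clip: tuple[float, float] | None = None,
) -> np.ndarray:
    """Proportional-error CV per level, log-interpolated between QC anchors.

    Interpolation is linear in log10(concentration); outside the anchor range
    the nearest anchor's CV is used. ``clip`` optionally bounds the result.
    """
    xs = np.log10(np.asarray(sorted(anchors), dtype=float))
    ys = np.asarray([anchors[k] for k in sorted(anchors)], dtype=float)
    cvs = np.interp(np.log10(np.asarray(levels, dtype=float)), xs, ys)
    if clip is not None:
        cvs = np.clip(cvs, *clip)
    return cvs


def simulate_ratio_series(
    levels: Sequence[float],
    cvs: Sequence[float] | float,
    slope: float,
    intercept: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noisy peak-height ratios for one calibration run.

    Each level's true ratio slope*level + intercept is multiplied by a mean-1
    log-normal error with that level's CV — the ratio-level shortcut for a full
    chromatogram render, used for fast linearity studies.
    """
    levels = np.asarray(levels, dtype=float)
    cvs = np.broadcast_to(np.asarray(cvs, dtype=float), levels.shape)
    true = slope * levels + intercept
    mults = np.array([_lognormal_multiplier(rng, cv) for cv in cvs])
    return true * mults
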