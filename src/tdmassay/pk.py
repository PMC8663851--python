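"""Monte-Carlo one-compartment pharmacokinetic simulation for assay range design.

The calibration range of a therapeutic-drug-monitoring assay should bracket the
concentrations actually seen in treated patients. This module predicts those
concentrations for a multiple-dose regimen under a one-compartment disposition
model with either zero-order (constant-rate) intravenous infusion or first-order
oral absorption, samples interindividual variability from moment-matched
log-normal distributions, and reduces the simulated population to percentile
bands. The range rule then converts the 2.5th/97.5th percentile envelope into
bounds on the assay's LLOQ and top calibrator:

* the LLOQ must lie below half the smallest lower (2.5th) percentile, and
* the top calibrator must lie above twice the largest upper (97.5th) percentile.

Concentrations are in ug/mL (equivalently mg/L), times in hours, clearance in
L/h and volume in L, so ``dose_mg / volume_L`` is directly ug/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSimulationError,
    InsufficientSampleError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "PKParameters",
    "DoseRegimen",
    "SimulationSummary",
    "CalibrationRange",
    "conc_iv_multidose",
    "conc_po_multidose",
    "sample_parameters",
    "simulate_population",
    "concentration_percentiles",
    "derive_calibration_range",
    "range_from_summaries",
]

Route = Literal["iv", "po"]

#: relative tolerance below which ka is treated as equal to k and the
#: L'Hopital limiting form of the oral profile is used
KA_K_DEGENERACY_RTOL = 1e-8


@dataclass(frozen=True)
class PKParameters:
    """Population means and SDs of the one-compartment parameters.

    ``cl`` is clearance (L/h), ``v`` the distribution volume (L); for oral
    dosing ``ka`` is the first-order absorption rate constant (1/h) and ``f``
    the bioavailable fraction. The elimination rate constant k = CL/V is
    derived, never stored. SDs are arithmetic-scale population SDs; set an SD
    to 0 for a fixed (deterministic) parameter.
    """

    cl_mean: float
    cl_sd: float
    v_mean: float
    v_sd: float
    ka_mean: float | None = None
    ka_sd: float | None = None
    f_mean: float | None = None
    f_sd: float | None = None

    def __post_init__(self) -> None:
        if self.cl_mean <= 0 or self.v_mean <= 0:
            raise InvalidParameterError("cl_mean and v_mean must be strictly positive")
        if self.cl_sd < 0 or self.v_sd < 0:
            raise InvalidParameterError("SDs must be non-negative")
        if self.ka_mean is not None and self.ka_mean <= 0:
            raise InvalidParameterError("ka_mean must be strictly positive")
        if self.f_mean is not None and not 0 < self.f_mean <= 1:
            raise InvalidParameterError("f_mean must lie in (0, 1]")
        for sd in (self.ka_sd, self.f_sd):
            if sd is not None and sd < 0:
                raise InvalidParameterError("SDs must be non-negative")

    def require_oral(self) -> None:
        if self.ka_mean is None or self.f_mean is None:
            raise InvalidParameterError(
                "oral simulation requires ka_mean and f_mean (with SDs)"
            )


@dataclass(frozen=True)
class DoseRegimen:
    """A repeated fixed-dose regimen: ``dose`` mg every ``interval`` h.

    For the iv route the dose is given as a zero-order infusion over
    ``infusion_duration`` h; for the oral route absorption is first-order and
    ``infusion_duration`` is ignored.
    """

    dose: float
    interval: float
    n_doses: int
    route: Route
    infusion_duration: float | None = None

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise InvalidParameterError("dose must be positive")
        if self.interval <= 0:
            raise InvalidParameterError("interval must be positive")
        if self.n_doses < 1:
            raise InvalidParameterError("n_doses must be >= 1")
        if self.route not in ("iv", "po"):
            raise InvalidParameterError(f"unknown route {self.route!r}")
        if self.route == "iv":
            if self.infusion_duration is None or self.infusion_duration <= 0:
                raise InvalidParameterError("iv regimen needs infusion_duration > 0")
            if self.infusion_duration >= self.interval:
                raise InvalidParameterError(
                    "infusion_duration must be shorter than the dosing interval"
                )

    @property
    def horizon(self) -> float:
        """End of the regimen's supported simulation window, h."""
        return self.n_doses * self.interval


def _single_dose_iv(t: np.ndarray, dose: float, tinf: float, cl: float, v: float) -> np.ndarray:
    """Zero-order infusion single-dose profile at times since dose start."""
    k = cl / v
    css = dose / tinf / cl  # plateau concentration of an unending infusion
    during = css * (1.0 - np.exp(-k * np.clip(t, 0.0, tinf)))
    c_end = css * (1.0 - np.exp(-k * tinf))
    after = c_end * np.exp(-k * np.clip(t - tinf, 0.0, None))
    out = np.where(t <= tinf, during, after)
    return np.where(t <= 0.0, 0.0, out)


def _single_dose_po(
    t: np.ndarray, dose: float, cl: float, v: float, ka: float, f: float
) -> np.ndarray:
    """First-order absorption single-dose profile (Bateman function)."""
    k = cl / v
    tpos = np.clip(t, 0.0, None)
    if abs(ka - k) < KA_K_DEGENERACY_RTOL * k:
        c = f * dose * k / v * tpos * np.exp(-k * tpos)
    else:
        c = f * dose * ka / (v * (ka - k)) * (np.exp(-k * tpos) - np.exp(-ka * tpos))
    return np.where(t <= 0.0, 0.0, c)


def _validate_t(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("times must be non-negative")
    return arr


def _superpose(t: np.ndarray, regimen: DoseRegimen, single) -> np.ndarray:
    total = np.zeros_like(t, dtype=float)
    for i in range(regimen.n_doses):
        total += single(t - i * regimen.interval)
    return total


def conc_iv_multidose(t, regimen: DoseRegimen, cl: float, v: float):
    """Concentration (ug/mL) at time(s) ``t`` under repeated iv infusions.

    Superposition over every dose started at or before ``t`` of the closed-form
    zero-order infusion/first-order elimination profile with k = cl/v.
    """
    if cl <= 0 or v <= 0:
        raise InvalidParameterError("cl and v must be strictly positive")
    if regimen.route != "iv":
        raise InvalidParameterError("regimen route must be 'iv'")
    arr = _validate_t(t)
    out = _superpose(
        arr, regimen, lambda tp: _single_dose_iv(tp, regimen.dose, regimen.infusion_duration, cl, v)
    )
    return out if np.ndim(t) else float(out)


def conc_po_multidose(t, regimen: DoseRegimen, cl: float, v: float, ka: float, f: float):
    """Concentration (ug/mL) at time(s) ``t`` under repeated oral doses.

    Superposition of Bateman single-dose profiles; when ka is within
    ``KA_K_DEGENERACY_RTOL`` of k the limiting form F*D*k*t*exp(-k*t)/V is
    used to avoid catastrophic cancellation.
    """
    if cl <= 0 or v <= 0:
        raise InvalidParameterError("cl and v must be strictly positive")
    if ka <= 0:
        raise InvalidParameterError("ka must be strictly positive")
    if not 0 < f <= 1:
        raise InvalidParameterError("f must lie in (0, 1]")
    if regimen.route != "po":
        raise InvalidParameterError("regimen route must be 'po'")
    arr = _validate_t(t)
    out = _superpose(arr, regimen, lambda tp: _single_dose_po(tp, regimen.dose, cl, v, ka, f))
    return out if np.ndim(t) else float(out)


def _lognormal_draws(
    rng: np.random.Generator, mean: float, sd: float, n: int, log_scale: bool
) -> np.ndarray:
    if sd < 0:
        raise InvalidParameterError("sd must be non-negative")
    if sd == 0:
        return np.full(n, float(mean))
    if log_scale:
        # mean is the median exp(mu); sd is the SD of log-parameter
        mu, sigma = np.log(mean), sd
    else:
        # moment matching: arithmetic mean/SD of the log-normal equal (mean, sd)
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        sigma = np.sqrt(sigma2)
    return rng.lognormal(mu, sigma, size=n)


def sample_parameters(
    params: PKParameters,
    route: Route,
    n: int,
    seed: int | np.random.Generator,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Draw ``n`` per-subject parameter sets from log-normal distributions.

    By default the log-normal is moment-matched so the sample's arithmetic mean
    and SD converge to the configured values (mu = ln(m^2/sqrt(m^2+s^2)),
    sigma^2 = ln(1+s^2/m^2)). With ``log_scale=True`` the configured mean is
    interpreted as the median and the SD as the SD of the log-parameter.
    Bioavailability draws are truncated at 1.0 to keep F physical. The same
    seed yields an identical frame.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = {
        "cl": _lognormal_draws(rng, params.cl_mean, params.cl_sd, n, log_scale),
        "v": _lognormal_draws(rng, params.v_mean, params.v_sd, n, log_scale),
    }
    if route == "po":
        params.require_oral()
        cols["ka"] = _lognormal_draws(rng, params.ka_mean, params.ka_sd or 0.0, n, log_scale)
        f = _lognormal_draws(rng, params.f_mean, params.f_sd or 0.0, n, log_scale)
        cols["f"] = np.minimum(f, 1.0)
    return pd.DataFrame(cols)


def simulate_population(
    params: PKParameters,
    regimen: DoseRegimen,
    times: Sequence[float],
    n_sim: int,
    seed: int | np.random.Generator,
    log_scale: bool = False,
) -> np.ndarray:
    """Simulate ``n_sim`` subjects; returns an (n_sim, len(times)) matrix.

    Row i is the closed-form multiple-dose profile under subject i's sampled
    parameters. Times must lie inside [0, n_doses*interval].
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise InvalidInputError("time grid must be non-empty")
    if np.any(t < 0) or np.any(t > regimen.horizon):
        raise InvalidInputError(
            f"times must lie within [0, {regimen.horizon}] h for this regimen"
        )
    subjects = sample_parameters(params, regimen.route, n_sim, seed, log_scale)
    profiles = np.empty((n_sim, t.size), dtype=float)
    for i, row in enumerate(subjects.itertuples(index=False)):
        if regimen.route == "iv":
            profiles[i] = conc_iv_multidose(t, regimen, row.cl, row.v)
        else:
            profiles[i] = conc_po_multidose(t, regimen, row.cl, row.v, row.ka, row.f)
    return profiles


@dataclass(frozen=True)
class SimulationSummary:
    """Per-time-point percentile envelope of a simulated population."""

    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_sim: int
    median: np.ndarray | None = None
    seed: int | None = None
    probs: tuple[float, float] = (0.025, 0.975)

    def at(self, t: float) -> tuple[float, float]:
        """Interpolated (lower, upper) percentile pair at time ``t`` h."""
        return (
            float(np.interp(t, self.times, self.lower)),
            float(np.interp(t, self.times, self.upper)),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times, f"p{self.probs[0] * 100:g}": self.lower}
        if self.median is not None:
            data["p50"] = self.median
        data[f"p{self.probs[1] * 100:g}"] = self.upper
        return pd.DataFrame(data)


def concentration_percentiles(
    times: Sequence[float],
    profiles: np.ndarray,
    probs: tuple[float, float] = (0.025, 0.975),
    seed: int | None = None,
    include_median: bool = True,
) -> SimulationSummary:
    """Empirical per-time-point quantile band over simulated profiles.

    Quantiles use linear interpolation between closest order statistics.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise InsufficientSampleError("need at least 2 profiles for percentiles")
    lo, hi = sorted(probs)
    if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0):
        raise InvalidInputError("percentile probabilities must lie in (0, 1)")
    lower = np.quantile(profiles, lo, axis=0, method="linear")
    upper = np.quantile(profiles, hi, axis=0, method="linear")
    median = (
        np.quantile(profiles, 0.5, axis=0, method="linear") if include_median else None
    )
    return SimulationSummary(
        times=np.asarray(times, dtype=float),
        lower=lower,
        upper=upper,
        median=median,
        n_sim=profiles.shape[0],
        seed=seed,
        probs=(lo, hi),
    )


@dataclass(frozen=True)
class CalibrationRange:
    """Admissible calibration-range bounds derived from the percentile band.

    ``lloq_upper_bound`` is the maximum admissible LLOQ (half the smallest
    lower percentile); ``top_lower_bound`` the minimum admissible top
    calibrator (twice the largest upper percentile).
    """

    lloq_upper_bound: float
    top_lower_bound: float

    def admits(self, lloq: float, top: float) -> bool:
        """True iff a candidate (LLOQ, top calibrator) pair satisfies the rule."""
        return lloq < self.lloq_upper_bound and top > self.top_lower_bound


def derive_calibration_range(
    lower_percentiles: Iterable[float], upper_percentiles: Iterable[float]
) -> CalibrationRange:
    """Apply the range rule to percentile values pooled over routes and days.

    The rule is deliberately conservative: the LLOQ bound comes from the
    smallest lower percentile over all supplied route/day combinations, the top
    bound from the largest upper percentile.
    """
    lowers = np.asarray(list(lower_percentiles), dtype=float)
    uppers = np.asarray(list(upper_percentiles), dtype=float)
    if lowers.size == 0 or uppers.size == 0:
        raise InvalidInputError("need at least one lower and one upper percentile")
    if np.any(lowers <= 0) or np.any(uppers <= 0):
        raise DegenerateSimulationError("percentiles must be strictly positive")
    return CalibrationRange(
        lloq_upper_bound=0.5 * float(lowers.min()),
        top_lower_bound=2.0 * float(uppers.max()),
    )


def range_from_summaries(
    summaries: Mapping[str, SimulationSummary] | Sequence[SimulationSummary],
    eval_times: Sequence[float] = (24.0, 168.0),
) -> CalibrationRange:
    """Range rule applied to summaries evaluated at the reporting times.

    ``eval_times`` defaults to the day-1 and day-7 troughs of a q24h regimen.
    """
    items = summaries.values() if isinstance(summaries, Mapping) else summaries
    lowers, uppers = [], []
    for summary in items:
        for t in eval_times:
            lo, hi = summary.at(t)
            lowers.append(lo)
            uppers.append(hi)
    return derive_calibration_range(lowers, uppers)
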