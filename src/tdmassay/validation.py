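"""Bioanalytical validation statistics and acceptance gating.

Implements the FDA-style accuracy/precision framework for QC samples:

    accuracy (%)  = measured concentration / theoretical concentration * 100
    precision (%) = sample SD / mean * 100   (relative standard deviation)

Intra-assay statistics are computed over the replicates within a run (day);
inter-assay statistics over the per-day means across days. Each QC level is
gated against acceptance limits — accuracy within 85-115% and precision
strictly below 15%, relaxed to 80-120% and <20% at the LLOQ. Recovery compares
extracted-sample peak heights with pre-spiked reference standards, and
selectivity checks blank chromatograms for interfering peaks at the analyte
and IS retention times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, InsufficientSampleError, InvalidInputError
from .peaks import RetentionWindow, detect_peak, estimate_baseline
from .synth import Chromatogram

__all__ = [
    "AcceptanceLimits",
    "QCResult",
    "RecoveryResult",
    "SelectivityReport",
    "accuracy",
    "precision",
    "rsd_from_stats",
    "aggregate_runs",
    "recovery",
    "aggregate_recovery",
    "selectivity_check",
    "evaluate_acceptance",
]

LevelType = Literal["lloq", "low", "medium", "high", "qc"]
Scope = Literal["intra", "inter"]


@dataclass(frozen=True)
class AcceptanceLimits:
    """Accuracy/precision acceptance limits; LLOQ levels use the relaxed set."""

    accuracy_low: float = 85.0
    accuracy_high: float = 115.0
    precision_max: float = 15.0
    lloq_accuracy_low: float = 80.0
    lloq_accuracy_high: float = 120.0
    lloq_precision_max: float = 20.0

    def __post_init__(self) -> None:
        if self.accuracy_low >= self.accuracy_high:
            raise InvalidInputError("accuracy_low must be below accuracy_high")
        if self.lloq_accuracy_low >= self.lloq_accuracy_high:
            raise InvalidInputError("lloq accuracy limits must be ordered")
        if self.precision_max <= 0 or self.lloq_precision_max <= 0:
            raise InvalidInputError("precision maxima must be positive")

    def for_level(self, level_type: LevelType) -> tuple[float, float, float]:
        if level_type == "lloq":
            return self.lloq_accuracy_low, self.lloq_accuracy_high, self.lloq_precision_max
        return self.accuracy_low, self.accuracy_high, self.precision_max


@dataclass(frozen=True)
class QCResult:
    """Accuracy/precision outcome for one QC level at one scope."""

    level_type: LevelType
    theoretical_conc: float
    observed_mean: float
    observed_sd: float
    accuracy_pct: float
    precision_pct: float
    scope: Scope
    n: int
    passed: bool | None = None


@dataclass(frozen=True)
class RecoveryResult:
    """Extraction recovery (%) of the analyte and IS at one level and scope."""

    level: float
    analyte_recovery_pct: float
    is_recovery_pct: float
    scope: Scope
    analyte_sd_pct: float = float("nan")
    is_sd_pct: float = float("nan")


def accuracy(measured: float, theoretical: float) -> float:
    """Percent accuracy: measured / theoretical * 100."""
    if theoretical <= 0:
        raise InvalidInputError("theoretical concentration must be positive")
    return measured / theoretical * 100.0


def precision(values: Sequence[float]) -> float:
    """Relative standard deviation (%): sample SD (n-1) over the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientSampleError("precision needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise InvalidInputError("mean of values is zero; RSD undefined")
    return float(arr.std(ddof=1) / mean * 100.0)


def rsd_from_stats(sd: float, mean: float) -> float:
    """RSD (%) from an already-computed SD and mean."""
    if mean == 0:
        raise InvalidInputError("mean is zero; RSD undefined")
    return sd / mean * 100.0


def _level_type(
    level: float, levels: Sequence[float], lloq_level: float | None
) -> LevelType:
    if lloq_level is not None and level == lloq_level:
        return "lloq"
    others = sorted(c for c in levels if lloq_level is None or c != lloq_level)
    names: dict[float, LevelType] = {}
    if len(others) == 3:
        names = dict(zip(others, ("low", "medium", "high")))
    elif len(others) == 2:
        names = dict(zip(others, ("low", "high")))
    return names.get(level, "qc")


def aggregate_runs(
    observations: pd.DataFrame,
    lloq_level: float | None = None,
    level_col: str = "nominal_conc_ug_ml",
    value_col: str = "back_calc_ug_ml",
    day_col: str = "day",
) -> list[QCResult]:
    """Intra- and inter-assay QC statistics from back-calculated concentrations.

    ``observations`` holds one row per QC replicate with its nominal level,
    day label and back-calculated concentration. For each level the intra
    scope pools the within-day statistics (mean of per-day means and of
    per-day RSDs, n = replicates per day); the inter scope takes statistics
    over the per-day means (n = days). Pass/fail is not decided here — see
    :func:`evaluate_acceptance`.
    """
    for col in (level_col, value_col, day_col):
        if col not in observations.columns:
            raise DesignError(f"observations frame is missing column {col!r}")
    results: list[QCResult] = []
    levels = sorted(observations[level_col].unique())
    for level in levels:
        sub = observations[observations[level_col] == level]
        day_groups = sub.groupby(day_col)[value_col]
        counts = day_groups.count()
        if (counts < 2).any():
            raise DesignError(
                f"level {level}: every day needs >= 2 replicates for intra statistics"
            )
        day_means = day_groups.mean()
        day_sds = day_groups.std(ddof=1)
        ltype = _level_type(level, levels, lloq_level)

        intra_mean = float(day_means.mean())
        intra_sd = float(day_sds.mean())
        results.append(
            QCResult(
                level_type=ltype,
                theoretical_conc=float(level),
                observed_mean=intra_mean,
                observed_sd=intra_sd,
                accuracy_pct=accuracy(intra_mean, level),
                precision_pct=float((day_sds / day_means * 100.0).mean()),
                scope="intra",
                n=int(counts.iloc[0]),
            )
        )
        if len(day_means) >= 2:
            inter_mean = float(day_means.mean())
            inter_sd = float(day_means.std(ddof=1))
            results.append(
                QCResult(
                    level_type=ltype,
                    theoretical_conc=float(level),
                    observed_mean=inter_mean,
                    observed_sd=inter_sd,
                    accuracy_pct=accuracy(inter_mean, level),
                    precision_pct=rsd_from_stats(inter_sd, inter_mean),
                    scope="inter",
                    n=int(len(day_means)),
                )
            )
    return results


def recovery(extracted_height: float, reference_height: float) -> float:
    """Extraction recovery (%): extracted response over reference response."""
    if reference_height <= 0:
        raise InvalidInputError("reference height must be positive")
    return extracted_height / reference_height * 100.0


def aggregate_recovery(
    heights: pd.DataFrame,
    level_col: str = "nominal_conc_ug_ml",
    day_col: str = "day",
    prep_col: str = "prep",
    analyte_col: str = "analyte_height",
    is_col: str = "is_height",
) -> list[RecoveryResult]:
    """Intra/inter recovery per level from matched extracted/reference heights.

    Per day and level, recovery is the ratio of mean extracted height to mean
    reference height. Intra reports the mean (and SD) of the per-day
    recoveries' underlying replicates pooled within a day; inter reports
    statistics across the per-day recoveries.
    """
    results: list[RecoveryResult] = []
    for level in sorted(heights[level_col].unique()):
        sub = heights[heights[level_col] == level]
        per_day_analyte, per_day_is = [], []
        for _, day_rows in sub.groupby(day_col):
            ext = day_rows[day_rows[prep_col] == "extracted"]
            ref = day_rows[day_rows[prep_col] == "reference"]
            if ext.empty or ref.empty:
                raise DesignError(f"level {level}: missing extracted/reference pair")
            per_day_analyte.append(recovery(ext[analyte_col].mean(), ref[analyte_col].mean()))
            per_day_is.append(recovery(ext[is_col].mean(), ref[is_col].mean()))
        a = np.asarray(per_day_analyte)
        i = np.asarray(per_day_is)
        results.append(
            RecoveryResult(
                level=float(level),
                analyte_recovery_pct=float(a.mean()),
                is_recovery_pct=float(i.mean()),
                scope="intra",
                analyte_sd_pct=float(a.std(ddof=1)) if a.size > 1 else float("nan"),
                is_sd_pct=float(i.std(ddof=1)) if i.size > 1 else float("nan"),
            )
        )
        if a.size > 1:
            results.append(
                RecoveryResult(
                    level=float(level),
                    analyte_recovery_pct=float(a.mean()),
                    is_recovery_pct=float(i.mean()),
                    scope="inter",
                    analyte_sd_pct=float(a.std(ddof=1)),
                    is_sd_pct=float(i.std(ddof=1)),
                )
            )
    return results


@dataclass(frozen=True)
class SelectivityReport:
    """Outcome of the blank-interference screen."""

    passed: bool
    interferences: tuple[str, ...] = ()


def selectivity_check(
    blanks: Iterable[Chromatogram],
    analyte_window: RetentionWindow,
    is_window: RetentionWindow,
    lloq_analyte_height: float,
    is_height: float,
    baseline_region: tuple[float, float] = (1.0, 5.0),
    analyte_fraction: float = 0.20,
    is_fraction: float = 0.05,
) -> SelectivityReport:
    """Screen blank chromatograms for interfering peaks.

    Passes iff no blank shows a detected peak whose height reaches
    ``analyte_fraction`` of the LLOQ-level analyte response in the analyte
    window, or ``is_fraction`` of the IS response in the IS window. A peak
    exactly at a threshold fails (passing requires strict inequality).
    """
    offenders: list[str] = []
    n = 0
    for chrom in blanks:
        n += 1
        level, noise = estimate_baseline(chrom, baseline_region, (analyte_window, is_window))
        for window, limit, label in (
            (analyte_window, analyte_fraction * lloq_analyte_height, "analyte"),
            (is_window, is_fraction * is_height, "is"),
        ):
            peak = detect_peak(chrom, window, level, noise)
            if peak is not None and peak.height >= limit:
                offenders.append(f"{chrom.sample_id or 'blank'}:{label}")
    if n == 0:
        raise InvalidInputError("selectivity check needs at least one blank")
    return SelectivityReport(passed=not offenders, interferences=tuple(offenders))


def evaluate_acceptance(result: QCResult, limits: AcceptanceLimits = AcceptanceLimits()) -> bool:
    """Gate one QC result: accuracy inside the closed interval, precision
    strictly below the maximum; LLOQ levels use the relaxed limits."""
    acc_lo, acc_hi, prec_max = limits.for_level(result.level_type)
    return acc_lo <= result.accuracy_pct <= acc_hi and result.precision_pct < prec_max
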