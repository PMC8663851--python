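"""End-to-end orchestration of the range-design and validation stages.

Two entry points mirror the study workflow:

* :func:`run_range` — Monte-Carlo population PK simulation per route, percentile
  envelope, and the derived admissible calibration range;
* :func:`run_validation` — synthetic validation campaign: render chromatograms,
  detect peaks, fit per-run calibration curves, back-calculate QC samples,
  aggregate accuracy/precision/recovery, decide LLOQ/LLOD and selectivity, and
  gate everything against the acceptance limits.

A peak-height table (the documented long-format CSV) is both an intermediate
output and an accepted input, so the validation stage can run without
chromatograms via :func:`analyze_peak_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationResults, fit_calibration
from .config import RunConfig
from .errors import DesignError
from .peaks import LimitDecision, RetentionWindow, detect_peak, determine_lloq_llod, estimate_baseline
from .pk import (
    CalibrationRange,
    SimulationSummary,
    concentration_percentiles,
    range_from_summaries,
    simulate_population,
)
from .report import (
    format_calibration_table,
    format_qc_table,
    format_range_report,
    format_recovery_table,
)
from .synth import (
    Chromatogram,
    generate_validation_dataset,
    interpolate_level_cvs,
    simulate_ratio_series,
)
from .validation import (
    QCResult,
    RecoveryResult,
    SelectivityReport,
    aggregate_recovery,
    aggregate_runs,
    evaluate_acceptance,
    selectivity_check,
)

__all__ = [
    "RangeResult",
    "ValidationResults",
    "run_range",
    "run_validation",
    "extract_peak_table",
    "analyze_peak_table",
    "linearity_study",
    "EXIT_PASS",
    "EXIT_FAIL",
    "EXIT_CONFIG",
    "EXIT_UNDETERMINED_LLOQ",
]

EXIT_PASS = 0
EXIT_FAIL = 2
EXIT_CONFIG = 3
EXIT_UNDETERMINED_LLOQ = 4


# ---------------------------------------------------------------------------
# range design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RangeResult:
    """Outcome of the range-design simulation."""

    summaries: Mapping[str, SimulationSummary]
    calibration_range: CalibrationRange
    eval_times: tuple[float, ...]
    seed: int
    warnings: tuple[str, ...] = ()

    def summary_frame(self) -> pd.DataFrame:
        frames = []
        for route, summary in self.summaries.items():
            frame = summary.to_frame()
            frame.insert(0, "route", route)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    def report(self, lloq_candidate: float | None = None, top_calibrator: float | None = None) -> str:
        return format_range_report(
            self.calibration_range, self.summaries, self.eval_times, lloq_candidate, top_calibrator
        )

    def write(self, outdir: str | Path, config: RunConfig | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(outdir / "range_summary.csv", index=False, float_format="%.6g")
        lloq = config.assay.lloq_candidate if config else None
        top = config.assay.top_calibrator if config else None
        (outdir / "range_report.txt").write_text(self.report(lloq, top) + "\n")


def run_range(config: RunConfig, seed: int | None = None) -> RangeResult:
    """Simulate each configured route and derive the admissible range."""
    pk = config.pk
    seed = config.seed if seed is None else seed
    times = np.arange(0.0, pk.n_doses * pk.interval_h + pk.time_step_h / 2, pk.time_step_h)
    params = pk.pk_parameters()
    summaries: dict[str, SimulationSummary] = {}
    for i, route in enumerate(pk.routes):
        profiles = simulate_population(
            params, pk.regimen(route), times, pk.n_sim, seed + i, pk.log_scale
        )
        summaries[route] = concentration_percentiles(
            times, profiles, pk.percentiles, seed=seed + i
        )
    crange = range_from_summaries(summaries, pk.eval_times_h)
    warnings = []
    if not crange.admits(config.assay.lloq_candidate, config.assay.top_calibrator):
        warnings.append(
            f"configured range {config.assay.lloq_candidate:g}-{config.assay.top_calibrator:g}"
            f" ug/mL violates the derived rule"
            f" (LLOQ < {crange.lloq_upper_bound:.4g}, top > {crange.top_lower_bound:.4g})"
        )
    return RangeResult(
        summaries=summaries,
        calibration_range=crange,
        eval_times=tuple(pk.eval_times_h),
        seed=seed,
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

def extract_peak_table(
    chromatograms: Iterable[Chromatogram],
    manifest: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Long-format peak table: one row per detected peak per sample.

    Columns: sample_id, analyte ('analyte' | 'is'), rt_min, height, area, s_n.
    Samples whose window holds no qualifying peak contribute no row for that
    compound (absence is a value, not an error).
    """
    geom = config.assay.geometry
    analysis = config.analysis
    windows = {
        "analyte": RetentionWindow(geom.analyte_rt, analysis.rt_tolerance_min),
        "is": RetentionWindow(geom.is_rt, analysis.rt_tolerance_min),
    }
    with_is = manifest.set_index("sample_id")["with_is"] if "with_is" in manifest else None
    rows = []
    for chrom in chromatograms:
        level, noise = estimate_baseline(
            chrom, analysis.baseline_region, tuple(windows.values())
        )
        for compound, window in windows.items():
            if compound == "is" and with_is is not None and not with_is.get(chrom.sample_id, True):
                continue
            peak = detect_peak(chrom, window, level, noise, analysis.smoothing_width)
            if peak is None:
                continue
            rows.append(
                {
                    "sample_id": chrom.sample_id,
                    "analyte": compound,
                    "rt_min": peak.retention_time,
                    "height": peak.height,
                    "area": peak.area,
                    "s_n": peak.s_n,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "analyte", "rt_min", "height", "area", "s_n"])


def _widen(peak_table: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Merge the long peak table with the manifest into one row per sample."""
    required = {"sample_id", "role", "nominal_conc_ug_ml", "day", "replicate"}
    missing = required - set(manifest.columns)
    if missing:
        raise DesignError(f"manifest is missing columns {sorted(missing)}")
    wide = peak_table.pivot_table(
        index="sample_id", columns="analyte", values=["height", "s_n", "rt_min"], aggfunc="first"
    )
    wide.columns = [f"{compound}_{quantity}" for quantity, compound in wide.columns]
    # keep only identity columns: the manifest may carry ground-truth heights
    id_cols = [c for c in ("sample_id", "role", "nominal_conc_ug_ml", "day", "replicate",
                           "with_is", "prep") if c in manifest.columns]
    merged = manifest[id_cols].merge(wide, left_on="sample_id", right_index=True, how="left")
    for col in ("analyte_height", "is_height", "analyte_s_n", "is_s_n"):
        if col not in merged:
            merged[col] = np.nan
    merged["ratio"] = merged["analyte_height"] / merged["is_height"]
    return merged


# ---------------------------------------------------------------------------
# validation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationResults:
    """Everything the validation stage measured, plus the verdict."""

    peak_table: pd.DataFrame
    calibrations: Mapping[int, CalibrationResults]
    qc_results: tuple[QCResult, ...]
    recovery_results: tuple[RecoveryResult, ...]
    limit_decision: LimitDecision
    selectivity: SelectivityReport
    back_calculated: pd.DataFrame
    sn_by_level: Mapping[float, float]
    seed: int | None = None

    @property
    def gates_passed(self) -> bool:
        qc_ok = all(r.passed for r in self.qc_results)
        return qc_ok and self.selectivity.passed

    @property
    def passed(self) -> bool:
        return self.gates_passed and self.limit_decision.lloq is not None

    @property
    def exit_code(self) -> int:
        if self.limit_decision.lloq is None:
            return EXIT_UNDETERMINED_LLOQ
        return EXIT_PASS if self.gates_passed else EXIT_FAIL

    def qc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scope": r.scope,
                "level_type": r.level_type,
                "theoretical_conc_ug_ml": r.theoretical_conc,
                "observed_mean_ug_ml": r.observed_mean,
                "observed_sd_ug_ml": r.observed_sd,
                "accuracy_pct": r.accuracy_pct,
                "precision_pct": r.precision_pct,
                "n": r.n,
                "pass": r.passed,
            }
            for r in self.qc_results
        )

    def recovery_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scope": r.scope,
                "level_ug_ml": r.level,
                "analyte_recovery_pct": r.analyte_recovery_pct,
                "analyte_sd_pct": r.analyte_sd_pct,
                "is_recovery_pct": r.is_recovery_pct,
                "is_sd_pct": r.is_sd_pct,
            }
            for r in self.recovery_results
        )

    def summary(self) -> str:
        decision = self.limit_decision
        blocks = [
            format_calibration_table(self.calibrations),
            "",
            format_qc_table(self.qc_results),
            "",
        ]
        if self.recovery_results:
            blocks += [format_recovery_table(self.recovery_results), ""]
        sn_lines = ["Signal-to-noise by level (worst run)"]
        for level in sorted(self.sn_by_level):
            sn = self.sn_by_level[level]
            sn_lines.append(f"  {level:g} ug/mL: S/N {'inf' if np.isinf(sn) else f'{sn:.1f}'}")
        blocks += ["\n".join(sn_lines), ""]
        blocks.append(
            f"LLOQ: {'undetermined' if decision.lloq is None else f'{decision.lloq:g} ug/mL'}"
            f" | LLOD: {'undetermined' if decision.llod is None else f'{decision.llod:g} ug/mL'}"
        )
        blocks.append(
            "Selectivity: " + ("pass" if self.selectivity.passed else
                               f"FAIL ({', '.join(self.selectivity.interferences)})")
        )
        blocks.append(f"Overall verdict: {'PASS' if self.passed else 'FAIL'}")
        return "\n".join(blocks)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.peak_table.to_csv(outdir / "peak_table.csv", index=False, float_format="%.9g")
        self.qc_frame().to_csv(outdir / "qc_results.csv", index=False, float_format="%.9g")
        if self.recovery_results:
            self.recovery_frame().to_csv(
                outdir / "recovery_results.csv", index=False, float_format="%.9g"
            )
        self.back_calculated.to_csv(
            outdir / "back_calculated.csv", index=False, float_format="%.9g"
        )
        (outdir / "validation_report.txt").write_text(self.summary() + "\n")


def analyze_peak_table(
    peak_table: pd.DataFrame,
    manifest: pd.DataFrame,
    config: RunConfig,
    blanks: Sequence[Chromatogram] | None = None,
    seed: int | None = None,
) -> ValidationResults:
    """Calibrate, back-calculate, aggregate and gate from a peak-height table.

    ``blanks`` optionally carries blank chromatograms for a trace-level
    selectivity check; without them selectivity is screened on the peak table
    itself (a blank fails if a peak was detected in either window above the
    interference thresholds).
    """
    assay, analysis = config.assay, config.analysis
    data = _widen(peak_table, manifest)

    cal_levels = set(assay.calibration_levels)
    cal = data[(data["role"] == "calibrator") & (data["nominal_conc_ug_ml"].isin(cal_levels))]
    if cal.empty:
        raise DesignError("no calibrator rows found in the peak table")

    calibrations: dict[int, CalibrationResults] = {}
    qc_parts = []
    for day, day_cal in cal.groupby("day"):
        curve = fit_calibration(
            day_cal["nominal_conc_ug_ml"], day_cal["ratio"], analysis.weighting
        )
        calibrations[int(day)] = curve
        day_qc = data[(data["role"] == "qc") & (data["day"] == day)].copy()
        if not day_qc.empty:
            day_qc["back_calc_ug_ml"] = curve.back_calculate(day_qc["ratio"].to_numpy())
            qc_parts.append(day_qc)
    if not qc_parts:
        raise DesignError("no QC rows found in the peak table")
    back = pd.concat(qc_parts, ignore_index=True)

    qc_results = aggregate_runs(back, lloq_level=assay.lloq_candidate)
    qc_results = [
        QCResult(**{**r.__dict__, "passed": evaluate_acceptance(r, analysis.limits)})
        for r in qc_results
    ]

    # worst-run S/N per calibrator level (detection-limit probe included);
    # a run where the peak went undetected counts as S/N 0
    all_cal = data[data["role"] == "calibrator"]
    sn_by_level = {
        float(level): float(sub["analyte_s_n"].fillna(0.0).min())
        for level, sub in all_cal.groupby("nominal_conc_ug_ml")
    }
    qc_stats = {
        r.theoretical_conc: (r.accuracy_pct, r.precision_pct)
        for r in qc_results
        if r.scope == "intra"
    }
    decision = determine_lloq_llod(
        sn_by_level,
        qc_stats,
        llod_sn=analysis.llod_sn,
        lloq_sn=analysis.lloq_sn,
        accuracy_limits=(analysis.limits.lloq_accuracy_low, analysis.limits.lloq_accuracy_high),
        precision_max=analysis.limits.lloq_precision_max,
    )

    rec_rows = data[data["role"].isin(["recovery_extracted", "recovery_reference"])].copy()
    recovery_results: tuple[RecoveryResult, ...] = ()
    if not rec_rows.empty:
        rec_rows["prep"] = np.where(
            rec_rows["role"] == "recovery_extracted", "extracted", "reference"
        )
        recovery_results = tuple(aggregate_recovery(rec_rows))

    lloq_cal = cal[cal["nominal_conc_ug_ml"] == assay.lloq_candidate]
    lloq_height = float(lloq_cal["analyte_height"].mean()) if not lloq_cal.empty else np.nan
    is_height = float(data["is_height"].dropna().mean())
    geom = assay.geometry
    analyte_window = RetentionWindow(geom.analyte_rt, analysis.rt_tolerance_min)
    is_window = RetentionWindow(geom.is_rt, analysis.rt_tolerance_min)
    if blanks:
        selectivity = selectivity_check(
            blanks,
            analyte_window,
            is_window,
            lloq_height,
            is_height,
            analysis.baseline_region,
            analysis.selectivity_analyte_fraction,
            analysis.selectivity_is_fraction,
        )
    else:
        offenders = []
        blank_rows = data[data["role"].isin(["blank", "double-blank"])]
        for _, row in blank_rows.iterrows():
            if (
                np.isfinite(row.get("analyte_height", np.nan))
                and row["analyte_height"] >= analysis.selectivity_analyte_fraction * lloq_height
            ):
                offenders.append(f"{row['sample_id']}:analyte")
            if (
                not row.get("with_is", False)
                and np.isfinite(row.get("is_height", np.nan))
                and row["is_height"] >= analysis.selectivity_is_fraction * is_height
            ):
                offenders.append(f"{row['sample_id']}:is")
        selectivity = SelectivityReport(passed=not offenders, interferences=tuple(offenders))

    return ValidationResults(
        peak_table=peak_table,
        calibrations=calibrations,
        qc_results=tuple(qc_results),
        recovery_results=recovery_results,
        limit_decision=decision,
        selectivity=selectivity,
        back_calculated=back[
            ["sample_id", "day", "replicate", "nominal_conc_ug_ml", "ratio", "back_calc_ug_ml"]
        ],
        sn_by_level=sn_by_level,
        seed=seed,
    )


def run_validation(config: RunConfig, seed: int | None = None) -> ValidationResults:
    """Generate the synthetic campaign and run the full validation analysis."""
    seed = config.seed if seed is None else seed
    assay = config.assay
    chromatograms, manifest = generate_validation_dataset(
        levels=assay.calibration_levels,
        qc_levels=assay.qc_levels,
        replicates_per_day=assay.replicates_per_day,
        days=assay.days,
        geometry=assay.geometry,
        response=assay.response,
        seed=seed,
        llod_probe=assay.llod_probe,
        recovery_levels=None if assay.include_recovery else [],
    )
    peak_table = extract_peak_table(chromatograms, manifest, config)
    blank_ids = set(manifest.loc[manifest["role"].isin(["blank", "double-blank"]), "sample_id"])
    blanks = [c for c in chromatograms if c.sample_id in blank_ids]
    return analyze_peak_table(peak_table, manifest, config, blanks=blanks, seed=seed)


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------

def linearity_study(
    n_runs: int = 500,
    seed: int = 0,
    levels: Sequence[float] = (0.025, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0),
    slope: float = 0.1,
    intercept: float = 0.003,
    cv_clip: tuple[float, float] | None = (0.01, 0.03),
    weighting: str = "none",
) -> pd.DataFrame:
    """R^2 of repeated synthetic calibrations under realistic proportional noise.

    Per-level CVs are interpolated from the QC precision anchors (optionally
    clipped); each run draws noisy ratios and fits the unweighted line. Returns
    one row per run with its seed and R^2.
    """
    cvs = interpolate_level_cvs(levels, clip=cv_clip)
    master = np.random.default_rng(seed)
    rows = []
    for i in range(n_runs):
        rng = np.random.default_rng(master.integers(2**31))
        ratios = simulate_ratio_series(levels, cvs, slope, intercept, rng)
        res = fit_calibration(levels, ratios, weighting)  # type: ignore[arg-type]
        rows.append({"run": i, "r_squared": res.r_squared, "slope": res.slope})
    return pd.DataFrame(rows)
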