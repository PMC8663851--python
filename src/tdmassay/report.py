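"""Human-readable report blocks mirroring a validation write-up.

Percentages print with one decimal and concentrations with three significant
figures; all pass/fail decisions are made upstream on unrounded values.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .calibration import CalibrationResults
from .pk import CalibrationRange, SimulationSummary
from .validation import QCResult, RecoveryResult, SelectivityReport

__all__ = [
    "format_calibration_table",
    "format_qc_table",
    "format_recovery_table",
    "format_range_report",
]


def _sig3(x: float) -> str:
    return f"{x:.3g}"


def format_calibration_table(calibrations: Mapping[int, CalibrationResults]) -> str:
    """Per-run calibration parameters with the across-run mean +/- SD."""
    lines = ["Calibration curve parameters (ratio = slope * conc + intercept)"]
    lines.append(f"{'run':>4} {'slope':>10} {'intercept':>10} {'R^2':>8}")
    slopes, intercepts, r2s = [], [], []
    for run in sorted(calibrations):
        res = calibrations[run]
        slopes.append(res.slope)
        intercepts.append(res.intercept)
        r2s.append(res.r_squared)
        lines.append(f"{run:>4} {res.slope:>10.4f} {res.intercept:>10.4f} {res.r_squared:>8.4f}")
    if len(slopes) > 1:
        lines.append(
            f"mean {np.mean(slopes):>10.4f} {np.mean(intercepts):>10.4f} {np.mean(r2s):>8.4f}"
        )
        lines.append(
            f"  sd {np.std(slopes, ddof=1):>10.4f} {np.std(intercepts, ddof=1):>10.4f}"
            f" {np.std(r2s, ddof=1):>8.4f}"
        )
    return "\n".join(lines)


def format_qc_table(results: Sequence[QCResult]) -> str:
    """Accuracy/precision per QC level, intra and inter scope."""
    lines = ["Accuracy and precision of QC samples"]
    header = (
        f"{'scope':>6} {'level':>8} {'theoretical':>12} {'observed':>16}"
        f" {'accuracy%':>10} {'precision%':>11} {'n':>3} {'pass':>5}"
    )
    lines.append(header)
    for res in results:
        observed = f"{_sig3(res.observed_mean)} ± {_sig3(res.observed_sd)}"
        verdict = "-" if res.passed is None else ("pass" if res.passed else "FAIL")
        lines.append(
            f"{res.scope:>6} {res.level_type:>8} {_sig3(res.theoretical_conc):>12}"
            f" {observed:>16} {res.accuracy_pct:>10.1f} {res.precision_pct:>11.1f}"
            f" {res.n:>3} {verdict:>5}"
        )
    return "\n".join(lines)


def format_recovery_table(results: Sequence[RecoveryResult]) -> str:
    """Extraction recovery of analyte and IS per level and scope."""
    lines = ["Extraction recovery (%)"]
    lines.append(f"{'scope':>6} {'level':>8} {'analyte':>16} {'IS':>16}")
    for res in results:
        def cell(mean: float, sd: float) -> str:
            return f"{mean:.1f} ± {sd:.1f}" if np.isfinite(sd) else f"{mean:.1f}"
        lines.append(
            f"{res.scope:>6} {_sig3(res.level):>8}"
            f" {cell(res.analyte_recovery_pct, res.analyte_sd_pct):>16}"
            f" {cell(res.is_recovery_pct, res.is_sd_pct):>16}"
        )
    return "\n".join(lines)


def format_range_report(
    crange: CalibrationRange,
    summaries: Mapping[str, SimulationSummary],
    eval_times: Sequence[float],
    lloq_candidate: float | None = None,
    top_calibrator: float | None = None,
) -> str:
    """Percentile envelope per route/time and the derived admissible range."""
    lines = ["Predicted concentration envelope (ug/mL)"]
    lines.append(f"{'route':>6} {'time_h':>7} {'lower':>8} {'upper':>8}")
    for route, summary in summaries.items():
        for t in eval_times:
            lo, hi = summary.at(t)
            lines.append(f"{route:>6} {t:>7g} {lo:>8.3f} {hi:>8.3f}")
    lines.append("")
    lines.append(
        f"Admissible LLOQ     : < {crange.lloq_upper_bound:.4g} ug/mL"
        " (half the smallest lower percentile)"
    )
    lines.append(
        f"Admissible top cal. : > {crange.top_lower_bound:.4g} ug/mL"
        " (twice the largest upper percentile)"
    )
    if lloq_candidate is not None and top_calibrator is not None:
        ok = crange.admits(lloq_candidate, top_calibrator)
        lines.append(
            f"Candidate range {lloq_candidate:g}-{top_calibrator:g} ug/mL: "
            + ("satisfies the range rule" if ok else "WARNING: violates the range rule")
        )
    return "\n".join(lines)
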