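"""Calibration-curve fitting and inverse prediction.

The assay's response is the analyte peak height divided by the internal
standard peak height; the calibration curve is a straight line

    ratio = slope * concentration + intercept

fitted by (optionally weighted) least squares across the calibrator levels.
Measured samples are quantified by inverse prediction (back-calculation)
through the fitted line. The model/results split follows the statsmodels
convention: :class:`CalibrationModel` holds the design, ``fit()`` returns a
:class:`CalibrationResults` carrying estimates, uncertainties and a summary
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidInputError, NonInvertibleError, SingularDesignError

__all__ = ["CalibrationModel", "CalibrationResults", "fit_calibration", "back_calculate"]

Weighting = Literal["none", "1/x", "1/x2"]


class CalibrationModel:
    """Linear calibration of peak-height ratio against nominal concentration.

    Parameters
    ----------
    levels : sequence of float
        Nominal calibrator concentrations, ug/mL. At least two distinct
        levels are required.
    ratios : sequence of float
        Observed analyte/IS peak-height ratios, same length as ``levels``.
    weighting : {"none", "1/x", "1/x2"}
        Least-squares weights. Unweighted by default; the inverse-concentration
        options counteract heteroscedasticity over a wide dynamic range.
    """

    def __init__(
        self,
        levels: Sequence[float],
        ratios: Sequence[float],
        weighting: Weighting = "none",
    ) -> None:
        self.levels = np.asarray(levels, dtype=float)
        self.ratios = np.asarray(ratios, dtype=float)
        if self.levels.size != self.ratios.size:
            raise InvalidInputError("levels and ratios must have equal length")
        if self.levels.size < 2:
            raise InvalidInputError("need at least two calibration points")
        if np.unique(self.levels).size < 2:
            raise SingularDesignError("all calibration levels are identical")
        if weighting not in ("none", "1/x", "1/x2"):
            raise InvalidInputError(f"unknown weighting {weighting!r}")
        if weighting != "none" and np.any(self.levels <= 0):
            raise InvalidInputError("inverse-concentration weighting needs positive levels")
        self.weighting = weighting

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        level_col: str = "nominal_conc_ug_ml",
        ratio_col: str = "ratio",
        weighting: Weighting = "none",
    ) -> "CalibrationModel":
        return cls(data[level_col], data[ratio_col], weighting=weighting)

    @property
    def weights(self) -> np.ndarray:
        if self.weighting == "none":
            return np.ones_like(self.levels)
        if self.weighting == "1/x":
            return 1.0 / self.levels
        return 1.0 / self.levels**2

    def fit(self) -> "CalibrationResults":
        exog = sm.add_constant(self.levels)
        res = sm.WLS(self.ratios, exog, weights=self.weights).fit()
        return CalibrationResults(model=self, _sm_results=res)


@dataclass(frozen=True)
class CalibrationResults:
    """Fitted calibration line with uncertainties and diagnostics."""

    model: CalibrationModel
    _sm_results: object

    @property
    def intercept(self) -> float:
        return float(self._sm_results.params[0])

    @property
    def slope(self) -> float:
        return float(self._sm_results.params[1])

    @property
    def bse(self) -> tuple[float, float]:
        """(intercept SE, slope SE)."""
        se = self._sm_results.bse
        return float(se[0]), float(se[1])

    @property
    def r_squared(self) -> float:
        """Squared correlation of fitted vs observed (weighted analogue under WLS)."""
        return float(self._sm_results.rsquared)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self._sm_results.resid, dtype=float)

    def predict(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return self.slope * c + self.intercept

    def back_calculate(self, ratio):
        """Inverse prediction: concentration(s) for observed ratio(s).

        Sub-blank ratios back-calculate to negative concentrations and are
        returned as-is; callers decide how to flag them.
        """
        scale = max(1.0, float(np.abs(self.model.ratios).max()))
        if abs(self.slope) < 1e-13 * scale:
            raise NonInvertibleError("zero slope: calibration curve is not invertible")
        out = (np.asarray(ratio, dtype=float) - self.intercept) / self.slope
        return out if np.ndim(ratio) else float(out)

    def accuracy_by_level(self) -> pd.DataFrame:
        """Per-level back-calculated concentration and % bias of the calibrators."""
        back = self.back_calculate(self.model.ratios)
        return pd.DataFrame(
            {
                "nominal_conc_ug_ml": self.model.levels,
                "back_calc_ug_ml": back,
                "accuracy_pct": back / self.model.levels * 100.0,
            }
        )

    def summary(self) -> str:
        ise, sse = self.bse
        lines = [
            "Calibration curve: ratio = slope * conc + intercept",
            f"  weighting : {self.model.weighting}",
            f"  n levels  : {self.model.levels.size}",
            f"  slope     : {self.slope:.6g} (SE {sse:.3g})",
            f"  intercept : {self.intercept:.6g} (SE {ise:.3g})",
            f"  R^2       : {self.r_squared:.6f}",
        ]
        return "\n".join(lines)


def fit_calibration(
    levels: Sequence[float], ratios: Sequence[float], weighting: Weighting = "none"
) -> CalibrationResults:
    """Convenience wrapper: build a :class:`CalibrationModel` and fit it."""
    return CalibrationModel(levels, ratios, weighting=weighting).fit()


def back_calculate(curve: CalibrationResults, ratio):
    """Functional alias for :meth:`CalibrationResults.back_calculate`."""
    return curve.back_calculate(ratio)
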