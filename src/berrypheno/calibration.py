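"""Linear calibration of detected berry counts toward true branch counts.

Counting berries in a single 2-D view systematically undercounts the branch
because hidden berries cannot be detected; the bias grows with berry number.
An ordinary least-squares line ``N_t ~ a + b * N_b`` (truth regressed on the
detected count) corrects for it.  The regression direction follows the
reported per-cultivar models, whose slopes below one with positive intercepts
are consistent with mapping an undercounted x to the larger truth.

R^2 and RMSE are computed in-sample on the fitted data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["CountCalibrator", "RegressionFit", "fit_linear", "apply_fit", "calibrate_groups"]


def _as_1d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence of counts (or a single-column 2-D array)")
    return arr


class CountCalibrator(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for the detected-count -> true-count line.

    ``fit(detected, truth)`` estimates intercept and slope by OLS and exposes
    ``intercept_``, ``slope_``, ``r2_``, ``rmse_``, ``n_`` plus the standard
    errors ``intercept_se_`` and ``slope_se_``; ``predict(detected)`` returns
    the calibrated (real-valued, unrounded) count estimate.
    """

    def fit(self, X, y):
        x = _as_1d(X)
        y = _as_1d(y)
        if len(x) != len(y):
            raise ValueError("detected and truth must have the same length")
        if len(x) < 3:
            raise ValueError("need at least 3 samples for a fit")
        if np.ptp(x) == 0:
            raise ValueError("degenerate fit: detected counts are all identical")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        r = float(res.rvalue)
        # constant truth makes R^2 a 0/0; define it as 0 (zero explained variance)
        self.r2_ = r * r if np.isfinite(r) else 0.0
        self.slope_se_ = float(res.stderr)
        self.intercept_se_ = float(res.intercept_stderr)
        resid = y - (self.intercept_ + self.slope_ * x)
        self.rmse_ = float(np.sqrt(np.mean(resid**2)))
        self.n_ = len(x)
        return self

    def predict(self, X):
        if not hasattr(self, "slope_"):
            raise AttributeError("calibrator is not fitted yet")
        return self.intercept_ + self.slope_ * _as_1d(X)


@dataclass(frozen=True)
class RegressionFit:
    """A fitted count-calibration line for one group of samples."""

    group: str
    intercept: float
    slope: float
    r2: float
    rmse: float
    n: int
    intercept_se: float
    slope_se: float


def fit_linear(detected, truth, group: str = "pooled") -> RegressionFit:
    """OLS fit of true count on detected count (y = a + b*x)."""
    est = CountCalibrator().fit(detected, truth)
    return RegressionFit(
        group=group,
        intercept=est.intercept_,
        slope=est.slope_,
        r2=est.r2_,
        rmse=est.rmse_,
        n=est.n_,
        intercept_se=est.intercept_se_,
        slope_se=est.slope_se_,
    )


def apply_fit(fit: RegressionFit, detected):
    """Calibrated count estimate a + b*x, as a real number (not rounded)."""
    x = np.asarray(detected, dtype=float)
    out = fit.intercept + fit.slope * x
    return float(out) if out.ndim == 0 else out


def calibrate_groups(
    df: pd.DataFrame,
    detected_col: str = "N_b",
    truth_col: str = "N_t",
    group_col: str = "cultivar",
) -> pd.DataFrame:
    """Pooled plus per-group calibration fits as a table.

    Groups with fewer than 3 samples are skipped with a warning.
    """
    fits = [fit_linear(df[detected_col], df[truth_col], group="pooled")]
    for name, sub in df.groupby(group_col, sort=True):
        if len(sub) < 3:
            warnings.warn(f"group {name!r} has only {len(sub)} samples; skipped")
            continue
        fits.append(fit_linear(sub[detected_col], sub[truth_col], group=str(name)))
    return pd.DataFrame(
        [
            {
                "group": f.group,
                "intercept": f.intercept,
                "slope": f.slope,
                "R2": f.r2,
                "RMSE": f.rmse,
                "n": f.n,
            }
            for f in fits
        ]
    )
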