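"""Linear calibration: OLS fit, inversion, and two linearity diagnostics.

Calibration is an unweighted straight line y = a + b*x fitted by ordinary
least squares to the (level, response) pairs.  Linearity is assessed two
ways, as is conventional for matrix-matched LC-MS/MS calibrations:

* the Huber response-factor plot — the per-level mean response divided by
  the level must stay within +/-5% of the median response factor across
  levels, which delimits the usable linear range;
* a lack-of-fit F test — the residual sum of squares is split into pure
  error (replicate scatter within levels) and lack of fit (distance of the
  level means from the fitted line); their mean-square ratio is compared to
  the upper-alpha F quantile at (levels-2, N-levels) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError, FitError, InversionError


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted straight-line calibration y = intercept + slope * x."""

    analyte_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residual_sd: float

    def predict(self, concentration):
        return self.intercept + self.slope * np.asarray(concentration)

    def inverse(self, response):
        return invert_calibration(self, response)


@dataclass(frozen=True)
class HuberAssessment:
    """Response-factor linearity check against the median factor."""

    factors_by_level: dict[float, float]
    target: float  # median response factor
    band_fraction: float
    pass_by_level: dict[float, bool]

    @property
    def passed(self) -> bool:
        return all(self.pass_by_level.values())


@dataclass(frozen=True)
class LackOfFitResult:
    ms_lack_of_fit: float
    ms_pure_error: float
    f_ratio: float
    df_lof: int
    df_pe: int
    f_critical: float

    @property
    def passed(self) -> bool:
        return self.f_ratio < self.f_critical


def _xy(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(records["nominal_conc"], dtype=float)
    y = np.asarray(records["response"], dtype=float)
    return x, y


def fit_calibration(records: pd.DataFrame, analyte_id: str | None = None) -> CalibrationCurve:
    """OLS straight-line fit of response on concentration.

    ``records`` holds one analyte's calibration standards (``nominal_conc``
    and ``response`` columns).  Requires >= 3 distinct levels and nonzero
    concentration variance.
    """
    x, y = _xy(records)
    if not np.isfinite(y).all():
        raise FitError("non-finite responses in calibration data")
    if np.unique(x).size < 3:
        raise FitError("need >= 3 distinct calibration levels")
    if np.ptp(x) == 0:
        raise FitError("zero concentration variance")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n = x.size
    residual_sd = float(np.sqrt(ss_res / (n - 2))) if n > 2 else 0.0
    if analyte_id is None:
        ids = records["analyte_id"].unique() if "analyte_id" in records else []
        analyte_id = str(ids[0]) if len(ids) else ""
    return CalibrationCurve(
        analyte_id=analyte_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        n_points=int(n),
        residual_sd=residual_sd,
    )


def invert_calibration(curve: CalibrationCurve, response):
    """Concentration = (response - a) / b.  Negative results are returned
    unclamped; callers that need a physical concentration clamp themselves."""
    if curve.slope == 0:
        raise InversionError("calibration slope is zero; curve not invertible")
    out = (np.asarray(response, dtype=float) - curve.intercept) / curve.slope
    return float(out) if out.ndim == 0 else out


def huber_linearity(records: pd.DataFrame, band_fraction: float = 0.05) -> HuberAssessment:
    """Response-factor plot assessment.

    Per level, factor = mean replicate response / level; the target is the
    median of the level factors; a level passes when its factor lies within
    target * (1 +/- band_fraction).
    """
    x, _ = _xy(records)
    if np.any(x <= 0):
        raise DesignError("Huber factors undefined at level <= 0")
    grouped = records.groupby("nominal_conc")["response"].mean()
    if grouped.size < 3:
        raise DesignError("need >= 3 levels for a Huber assessment")
    factors = {float(lv): float(m / lv) for lv, m in grouped.items()}
    target = float(np.median(list(factors.values())))
    lo, hi = target * (1 - band_fraction), target * (1 + band_fraction)
    flags = {lv: bool(lo <= f <= hi) for lv, f in factors.items()}
    return HuberAssessment(
        factors_by_level=factors,
        target=target,
        band_fraction=band_fraction,
        pass_by_level=flags,
    )


def lack_of_fit_anova(records: pd.DataFrame, alpha: float = 0.05) -> LackOfFitResult:
    """Lack-of-fit F test of the straight-line calibration.

    Partitions the OLS residual SS into pure error (within-level replicate
    scatter, N - L df) and lack of fit (level means vs fitted line, L - 2
    df); F = MS_lof / MS_pe is compared to the upper-alpha F quantile.
    """
    x, y = _xy(records)
    levels = np.unique(x)
    if levels.size < 3:
        raise DesignError("need >= 3 levels for a lack-of-fit test")
    counts = records.groupby("nominal_conc")["response"].size()
    df_pe = int((counts - 1).sum())
    if df_pe < 1:
        raise DesignError("no replication: pure error not estimable")
    curve = fit_calibration(records)
    fitted = curve.predict(x)
    ss_res = float(np.sum((y - fitted) ** 2))
    level_means = records.groupby("nominal_conc")["response"].transform("mean")
    ss_pe = float(np.sum((y - level_means) ** 2))
    ss_lof = max(0.0, ss_res - ss_pe)
    df_lof = int(levels.size - 2)
    ms_pe = ss_pe / df_pe
    ms_lof = ss_lof / df_lof if df_lof > 0 else 0.0
    if ms_pe > 0:
        f_ratio = ms_lof / ms_pe
    else:
        f_ratio = 0.0 if ms_lof == 0 else float("inf")
    f_crit = float(stats.f.ppf(1.0 - alpha, df_lof, df_pe)) if df_lof > 0 else float("inf")
    return LackOfFitResult(
        ms_lack_of_fit=ms_lof,
        ms_pure_error=ms_pe,
        f_ratio=f_ratio,
        df_lof=df_lof,
        df_pe=df_pe,
        f_critical=f_crit,
    )
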