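"""Blank-based detection limits and the matrix effect.

LOD/LOQ follow the blank-signal convention: the decision signal is
Y = mean(blank) + n * SD(blank) with n = 3 for detection and n = 10 for
quantification, converted to concentration through the calibration curve.
The matrix effect is the relative slope change between a calibration in
pure solvent and one in blank matrix extract,
ME% = 100 * (b_matrix - b_solvent) / b_solvent, classified as negligible
(|ME| < 10), mild (10 <= |ME| <= 20) or strong (|ME| > 20).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, invert_calibration
from .exceptions import DesignError, InversionError

N_LOD = 3
N_LOQ = 10


@dataclass(frozen=True)
class BlankStatistics:
    y_blank_mean: float
    s_blank: float
    n_blanks: int


@dataclass(frozen=True)
class DetectionLimits:
    """LOD/LOQ in concentration units (ng/g f.w., numerically = ug/L here)."""

    lod: float
    loq: float
    n_lod: int = N_LOD
    n_loq: int = N_LOQ


@dataclass(frozen=True)
class MatrixEffectResult:
    me_percent: float
    classification: str  # negligible | mild | strong


def blank_stats(records: pd.DataFrame) -> BlankStatistics:
    """Sample mean and SD (n-1 denominator) of blank responses."""
    y = np.asarray(records["response"], dtype=float)
    if y.size < 2:
        raise DesignError("need >= 2 blanks")
    return BlankStatistics(
        y_blank_mean=float(y.mean()),
        s_blank=float(y.std(ddof=1)),
        n_blanks=int(y.size),
    )


def detection_limits(stats_: BlankStatistics, curve: CalibrationCurve) -> DetectionLimits:
    """LOD/LOQ from blank statistics through the calibration curve.

    lod = max(0, (mean + 3 SD - a) / b), loq with 10 SD; negative
    back-computed values clamp to zero (concentrations are physical).
    """
    if curve.slope <= 0:
        raise InversionError("calibration slope must be > 0 for detection limits")
    y_lod = stats_.y_blank_mean + N_LOD * stats_.s_blank
    y_loq = stats_.y_blank_mean + N_LOQ * stats_.s_blank
    lod = max(0.0, invert_calibration(curve, y_lod))
    loq = max(0.0, invert_calibration(curve, y_loq))
    return DetectionLimits(lod=lod, loq=loq)


def classify_matrix_effect(me_percent: float) -> str:
    a = abs(me_percent)
    if a < 10:
        return "negligible"
    if a <= 20:
        return "mild"
    return "strong"


def matrix_effect(
    solvent_curve: CalibrationCurve, matrix_curve: CalibrationCurve
) -> MatrixEffectResult:
    """Slope-ratio matrix effect: 100 * (b_matrix - b_solvent) / b_solvent."""
    if solvent_curve.slope == 0:
        raise InversionError("solvent slope is zero; matrix effect undefined")
    me = 100.0 * (matrix_curve.slope - solvent_curve.slope) / solvent_curve.slope
    return MatrixEffectResult(me_percent=float(me), classification=classify_matrix_effect(me))
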