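"""Synthetic measurement generator for the validation pipeline.

The generator emulates a matrix-matched LC-MS/MS validation experiment on
spiked lettuce extracts for four cyanotoxins (the microcystin congeners
MC-LR, MC-RR, MC-YR and cylindrospermopsin, CYN):

* 12-point calibration curves in triplicate over 0.2-75 ug/L, in pure
  solvent and in blank matrix extract (the matrix shifts the slope by a
  multiplicative ratio);
* >= 10 independent procedural blanks with Gaussian baseline signal;
* a 3-day x 3-replicate precision/recovery study at 5, 20 and 50 ug/L,
  with an additive shared day effect and independent within-day noise on
  the concentration scale, attenuated by a per-level recovery fraction;
* the eight Youden ruggedness combinations at 20 ug/L.

All noise lives on the concentration scale and is pushed through the linear
response map, so the variance components estimated downstream are directly
interpretable in ug/L.  Spike levels in ug/L of spiking solution equal
ng/g fresh weight of leaf in the emulated design (1 mL onto ~1 g of leaf),
so no unit conversion is ever computed.

Records are rows of a tidy :class:`pandas.DataFrame` with the fixed schema
:data:`cyanoval.io.MEASUREMENT_COLUMNS`.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DesignError, ModelError
from .io import MEASUREMENT_COLUMNS
from .robustness import FACTORS, YoudenDesign, build_design

# --------------------------------------------------------------------------
# reference study values used as simulator defaults
# --------------------------------------------------------------------------

ANALYTES = ("MC-LR", "MC-RR", "MC-YR", "CYN")

#: solvent-curve regression coefficients (slope, intercept, r^2) per analyte
REFERENCE_CURVES: dict[str, tuple[float, float, float]] = {
    "MC-LR": (127.47, 1.0247, 0.9996),
    "MC-RR": (157.73, 1.4145, 0.9991),
    "MC-YR": (103.83, 0.1822, 0.9988),
    "CYN": (86.079, 0.7383, 0.9999),
}

#: matrix effect in percent; matrix slope = solvent slope * (1 + ME/100)
REFERENCE_MATRIX_EFFECT: dict[str, float] = {
    "MC-LR": 4.23,
    "MC-RR": 17.17,
    "MC-YR": -12.32,
    "CYN": -11.40,
}

#: (s_w, s_b, s_ip, rsd_ip_percent) per (analyte, level ug/L) from the
#: reference validation study; s_b is sqrt of the between-day mean square.
REFERENCE_PRECISION: dict[tuple[str, float], tuple[float, float, float, float]] = {
    ("MC-LR", 5): (0.20, 1.10, 0.66, 21.68),
    ("MC-LR", 20): (2.06, 2.20, 2.11, 13.21),
    ("MC-LR", 50): (4.62, 8.85, 6.35, 15.12),
    ("MC-RR", 5): (0.14, 0.21, 0.17, 8.31),
    ("MC-RR", 20): (1.38, 2.36, 1.77, 9.54),
    ("MC-RR", 50): (3.30, 8.47, 5.58, 12.58),
    ("MC-YR", 5): (0.23, 0.74, 0.46, 19.86),
    ("MC-YR", 20): (1.32, 1.79, 1.49, 11.14),
    ("MC-YR", 50): (2.67, 4.93, 3.59, 9.64),
    ("CYN", 5): (0.28, 0.65, 0.44, 19.30),
    ("CYN", 20): (0.82, 1.20, 0.96, 6.92),
    ("CYN", 50): (1.65, 5.85, 3.64, 11.62),
}

#: (LOD, LOQ) in ng/g f.w. per analyte
REFERENCE_LIMITS: dict[str, tuple[float, float]] = {
    "MC-LR": (0.06, 0.16),
    "MC-RR": (0.23, 0.50),
    "MC-YR": (0.42, 0.91),
    "CYN": (0.07, 0.19),
}

#: MRM transitions, quantifier first — fixture metadata only
TRANSITIONS: tuple[dict, ...] = (
    {"analyte_id": "MC-LR", "precursor_mz": 996.5, "product_mz": 135.0, "role": "quantifier"},
    {"analyte_id": "MC-LR", "precursor_mz": 996.5, "product_mz": 213.1, "role": "confirmatory"},
    {"analyte_id": "MC-LR", "precursor_mz": 996.5, "product_mz": 996.5, "role": "confirmatory"},
    {"analyte_id": "MC-RR", "precursor_mz": 520.2, "product_mz": 135.0, "role": "quantifier"},
    {"analyte_id": "MC-RR", "precursor_mz": 1039.5, "product_mz": 135.0, "role": "confirmatory"},
    {"analyte_id": "MC-YR", "precursor_mz": 1046.5, "product_mz": 135.0, "role": "quantifier"},
    {"analyte_id": "MC-YR", "precursor_mz": 1046.5, "product_mz": 213.0, "role": "confirmatory"},
    {"analyte_id": "MC-YR", "precursor_mz": 1046.5, "product_mz": 1046.5, "role": "confirmatory"},
    {"analyte_id": "CYN", "precursor_mz": 416.2, "product_mz": 194.0, "role": "quantifier"},
    {"analyte_id": "CYN", "precursor_mz": 416.2, "product_mz": 176.0, "role": "confirmatory"},
)


# --------------------------------------------------------------------------
# model and design
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyteModel:
    """Generative model for one analyte's instrument behaviour.

    ``slope``/``intercept`` define the solvent calibration response
    y = intercept + slope * c; in matrix the slope is multiplied by
    ``matrix_slope_ratio``.  Noise SDs are on the concentration scale and
    looked up by spike level (nearest key when a level is absent, so the
    calibration range can extend beyond the validation levels).
    """

    analyte_id: str
    slope: float
    intercept: float
    recovery_fraction_by_level: Mapping[float, float]
    within_day_sd_by_level: Mapping[float, float]
    day_effect_sd_by_level: Mapping[float, float]
    blank_mean: float = 0.0
    blank_sd: float = 0.0
    matrix_slope_ratio: float = 1.0
    #: optional noise map for calibration standards (spiked extracts measured
    #: directly, without the full extraction); empty -> within_day_sd is used
    calibration_sd_by_level: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.slope > 0):
            raise ModelError(f"{self.analyte_id}: slope must be > 0")
        if not (self.matrix_slope_ratio > 0):
            raise ModelError(f"{self.analyte_id}: matrix_slope_ratio must be > 0")
        if self.blank_sd < 0:
            raise ModelError(f"{self.analyte_id}: blank_sd must be >= 0")
        for name, m in (
            ("within_day_sd", self.within_day_sd_by_level),
            ("day_effect_sd", self.day_effect_sd_by_level),
            ("calibration_sd", self.calibration_sd_by_level),
        ):
            if any(v < 0 for v in m.values()):
                raise ModelError(f"{self.analyte_id}: {name} must be >= 0")
        for lvl, r in self.recovery_fraction_by_level.items():
            if not (0 < r <= 1.5):
                raise ModelError(
                    f"{self.analyte_id}: recovery fraction at level {lvl} "
                    f"must be in (0, 1.5], got {r}"
                )

    # -- lookups ----------------------------------------------------------

    @staticmethod
    def _nearest(table: Mapping[float, float], level: float) -> float:
        if not table:
            return 0.0
        if level in table:
            return table[level]
        key = min(table, key=lambda k: abs(k - level))
        return table[key]

    def within_day_sd(self, level: float) -> float:
        return self._nearest(self.within_day_sd_by_level, level)

    def day_effect_sd(self, level: float) -> float:
        return self._nearest(self.day_effect_sd_by_level, level)

    def calibration_sd(self, level: float) -> float:
        if self.calibration_sd_by_level:
            return self._nearest(self.calibration_sd_by_level, level)
        return self.within_day_sd(level)

    def recovery_fraction(self, level: float) -> float:
        return self._nearest(self.recovery_fraction_by_level, level)

    def effective_slope(self, matrix: bool) -> float:
        return self.slope * self.matrix_slope_ratio if matrix else self.slope

    def response(self, concentration, matrix: bool = True):
        """Noise-free instrument response for a (true) concentration."""
        return self.intercept + self.effective_slope(matrix) * np.asarray(concentration)


@dataclass(frozen=True)
class StudyDesign:
    """Layout of the validation experiment."""

    calibration_levels: tuple[float, ...] = (
        0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 75.0,
    )
    calibration_replicates: int = 3
    validation_levels: tuple[float, ...] = (5.0, 20.0, 50.0)
    days: int = 3
    replicates_per_day: int = 3
    n_blanks: int = 10
    youden_level: float = 20.0
    youden_replicates_per_combination: int = 1

    def __post_init__(self):
        if len(set(self.calibration_levels)) < 3:
            raise DesignError("need >= 3 distinct calibration levels")
        if self.days < 2:
            raise DesignError("need >= 2 days")
        if self.replicates_per_day < 2:
            raise DesignError("need >= 2 replicates per day")
        if self.n_blanks < 2:
            raise DesignError("need >= 2 blanks")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _frame(analyte_id, sample_type, conc, day, rep, response, combo="") -> pd.DataFrame:
    n = len(response)
    df = pd.DataFrame(
        {
            "analyte_id": np.full(n, analyte_id, dtype=object),
            "sample_type": np.full(n, sample_type, dtype=object),
            "nominal_conc": np.asarray(conc, dtype=float),
            "day": np.asarray(day, dtype=int),
            "replicate": np.asarray(rep, dtype=int),
            "response": np.asarray(response, dtype=float),
            "youden_combo": combo if not isinstance(combo, str) else np.full(n, combo, dtype=object),
        }
    )
    return df[list(MEASUREMENT_COLUMNS)]


# --------------------------------------------------------------------------
# simulators
# --------------------------------------------------------------------------


def simulate_calibration(
    model: AnalyteModel,
    design: StudyDesign,
    matrix: bool = True,
    seed=0,
) -> pd.DataFrame:
    """Calibration standards: one record per level x replicate.

    response = intercept + slope_eff * (level + eps), with eps Gaussian on
    the concentration scale at the within-day SD of the (nearest) level.
    """
    rng = _rng(seed)
    levels = np.repeat(design.calibration_levels, design.calibration_replicates)
    reps = np.tile(
        np.arange(1, design.calibration_replicates + 1), len(design.calibration_levels)
    )
    sds = np.array([model.calibration_sd(lv) for lv in levels])
    eps = rng.normal(0.0, 1.0, size=levels.size) * sds
    slope_eff = model.effective_slope(matrix)
    resp = model.intercept + slope_eff * (levels + eps)
    stype = "matrix_std" if matrix else "solvent_std"
    return _frame(model.analyte_id, stype, levels, np.ones_like(reps), reps, resp)


def simulate_blanks(model: AnalyteModel, n: int = 10, seed=0) -> pd.DataFrame:
    """``n`` independent procedural blanks, response ~ N(blank_mean, blank_sd)."""
    if n < 2:
        raise DesignError("need >= 2 blanks for a standard deviation")
    rng = _rng(seed)
    resp = rng.normal(model.blank_mean, model.blank_sd, size=n) if model.blank_sd > 0 \
        else np.full(n, model.blank_mean, dtype=float)
    return _frame(
        model.analyte_id, "blank",
        np.zeros(n), np.ones(n, dtype=int), np.arange(1, n + 1), resp,
    )


def simulate_precision_study(
    model: AnalyteModel,
    design: StudyDesign,
    seed=0,
) -> pd.DataFrame:
    """Spiked-sample study: levels x days x replicates.

    The measured concentration for day d, replicate r at level L is
    L * recovery + delta_d + eps_dr, with delta_d shared by a day and eps_dr
    independent; it is emitted as an instrument response through the matrix
    calibration map so downstream code exercises the signal->concentration
    inversion.
    """
    rng = _rng(seed)
    frames = []
    slope_eff = model.effective_slope(matrix=True)
    for level in design.validation_levels:
        rec = model.recovery_fraction(level)
        dsd = model.day_effect_sd(level)
        wsd = model.within_day_sd(level)
        deltas = rng.normal(0.0, dsd, size=design.days) if dsd > 0 else np.zeros(design.days)
        eps = (
            rng.normal(0.0, wsd, size=(design.days, design.replicates_per_day))
            if wsd > 0
            else np.zeros((design.days, design.replicates_per_day))
        )
        conc = level * rec + deltas[:, None] + eps
        days = np.repeat(np.arange(1, design.days + 1), design.replicates_per_day)
        reps = np.tile(np.arange(1, design.replicates_per_day + 1), design.days)
        resp = model.intercept + slope_eff * conc.ravel()
        frames.append(
            _frame(model.analyte_id, "spike", np.full(days.size, level), days, reps, resp)
        )
    return pd.concat(frames, ignore_index=True)


def simulate_youden_runs(
    model: AnalyteModel,
    design: StudyDesign,
    factor_shifts: Mapping[str, float] | None = None,
    seed=0,
    youden_design: YoudenDesign | None = None,
) -> pd.DataFrame:
    """The eight ruggedness combinations at the Youden spike level.

    ``factor_shifts`` maps F1/F2/F3 to a concentration shift (ug/L) added to
    the measured concentration whenever that factor sits at its + level.
    Noise is the within-day SD at the Youden level.
    """
    factor_shifts = dict(factor_shifts or {})
    unknown = set(factor_shifts) - set(FACTORS)
    if unknown:
        raise ConfigError(f"unknown Youden factors: {sorted(unknown)}")
    yd = youden_design or build_design()
    rng = _rng(seed)
    level = design.youden_level
    rec = model.recovery_fraction(level)
    wsd = model.within_day_sd(level)
    slope_eff = model.effective_slope(matrix=True)

    combos = list(yd.combinations)
    nrep = design.youden_replicates_per_combination
    rows_combo, rows_rep, rows_conc = [], [], []
    for combo in combos:
        shift = sum(
            factor_shifts.get(f, 0.0) for f in yd.factors if yd.sign(combo, f) > 0
        )
        for r in range(1, nrep + 1):
            eps = rng.normal(0.0, wsd) if wsd > 0 else 0.0
            rows_combo.append(combo)
            rows_rep.append(r)
            rows_conc.append(level * rec + shift + eps)
    resp = model.intercept + slope_eff * np.asarray(rows_conc)
    return _frame(
        model.analyte_id, "youden",
        np.full(len(rows_combo), level), np.ones(len(rows_combo), dtype=int),
        rows_rep, resp, combo=np.asarray(rows_combo, dtype=object),
    )


def simulate_bundle(
    models: Mapping[str, AnalyteModel] | None = None,
    design: StudyDesign | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full validation bundle for a set of analytes.

    Contains, per analyte: solvent + matrix calibrations, blanks, the
    precision/recovery study and the Youden runs.  One global seed is split
    into independent substreams per analyte and stage, so any stage re-run
    in isolation reproduces its own records.
    """
    models = models or default_models()
    design = design or StudyDesign()
    root = np.random.SeedSequence(seed)
    frames = []
    for (name, model), ss in zip(sorted(models.items()), root.spawn(len(models))):
        s_cal_m, s_cal_s, s_blank, s_prec, s_youden = ss.spawn(5)
        frames.append(simulate_calibration(model, design, True, np.random.default_rng(s_cal_m)))
        frames.append(simulate_calibration(model, design, False, np.random.default_rng(s_cal_s)))
        frames.append(simulate_blanks(model, design.n_blanks, np.random.default_rng(s_blank)))
        frames.append(simulate_precision_study(model, design, np.random.default_rng(s_prec)))
        frames.append(simulate_youden_runs(model, design, None, np.random.default_rng(s_youden)))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# default models mirroring the reference study
# --------------------------------------------------------------------------


def _blank_defaults(slope_matrix: float, intercept: float, lod: float, loq: float):
    """Blank mean/SD that place LOD/LOQ at the given values on the matrix curve.

    Inverts lod = (mean + 3 sd - a)/b and loq - lod = 7 sd / b.
    """
    sd = slope_matrix * (loq - lod) / 7.0
    mean = slope_matrix * lod + intercept - 3.0 * sd
    return mean, sd


def default_models() -> dict[str, AnalyteModel]:
    """Generative models reproducing the reference study's statistics.

    Slopes/intercepts are the reference regression equations; within-day and
    day-effect SDs back out of the reference precision table (the day
    component is sqrt(max(0, (s_b^2 - s_w^2)/r)) with r = 3); recovery
    fractions come from the reported intermediate-precision RSDs (mean
    measured = s_ip / rsd); blank signals place LOD/LOQ at the reference
    limits on the matrix curve.
    """
    r = 3  # replicates per day in the reference design
    design = StudyDesign()
    lv = np.asarray(design.calibration_levels)
    # concentration-proportional calibration noise whose CV reproduces the
    # reference r^2: 1 - r^2 = cv^2 * E[L^2] / Var(L) over the level grid
    r2_factor = float(lv.var() / np.mean(lv**2))
    models = {}
    for analyte in ANALYTES:
        slope, intercept, r2 = REFERENCE_CURVES[analyte]
        cv = math.sqrt(max(0.0, 1.0 - r2) * r2_factor)
        cal_sd = {float(level): cv * float(level) for level in lv}
        ratio = 1.0 + REFERENCE_MATRIX_EFFECT[analyte] / 100.0
        wsd, dsd, rec = {}, {}, {}
        for (a, level), (s_w, s_b, s_ip, rsd) in REFERENCE_PRECISION.items():
            if a != analyte:
                continue
            wsd[level] = s_w
            dsd[level] = math.sqrt(max(0.0, (s_b**2 - s_w**2) / r))
            mean_measured = s_ip / (rsd / 100.0)
            rec[level] = round(mean_measured / level, 3)
        lod, loq = REFERENCE_LIMITS[analyte]
        bmean, bsd = _blank_defaults(slope * ratio, intercept, lod, loq)
        models[analyte] = AnalyteModel(
            analyte_id=analyte,
            slope=slope,
            intercept=intercept,
            recovery_fraction_by_level=rec,
            within_day_sd_by_level=wsd,
            day_effect_sd_by_level=dsd,
            blank_mean=bmean,
            blank_sd=bsd,
            matrix_slope_ratio=ratio,
            calibration_sd_by_level=cal_sd,
        )
    return models


def noiseless(model: AnalyteModel) -> AnalyteModel:
    """Copy of ``model`` with every noise source switched off."""
    return replace(
        model,
        within_day_sd_by_level={k: 0.0 for k in model.within_day_sd_by_level} or {0.0: 0.0},
        day_effect_sd_by_level={k: 0.0 for k in model.day_effect_sd_by_level} or {0.0: 0.0},
        calibration_sd_by_level={},
        blank_sd=0.0,
    )


def transitions_table() -> pd.DataFrame:
    """MRM transition metadata (quantifier/confirmatory) as a DataFrame."""
    return pd.DataFrame(list(TRANSITIONS))
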