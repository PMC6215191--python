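"""Top-level model/results interface and the machine-readable report.

:class:`MethodValidation` is built from a tidy measurement table (one row
per instrument observation) and a :class:`ValidationConfig`; ``fit()``
executes every assessment the data support — calibration and linearity,
blank-based LOD/LOQ, matrix effect, precision/recovery ANOVA per spike
level, and the Youden ruggedness test — and returns a
:class:`ValidationResults` carrying a pydantic report (the JSON contract),
per-analyte verdicts and a text ``summary()``.

Blocks whose input data are absent are marked ``"not assessed (missing
data)"`` rather than failing the whole run; every verdict is derivable
from the report blocks alone.  Reports are deterministic: identical inputs
produce byte-identical JSON (provenance carries content digests, not
timestamps).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import calibration as cal
from . import precision as prec
from . import robustness as rob
from . import sensitivity as sens
from .exceptions import ConfigError, CyanovalError
from .io import MEASUREMENT_COLUMNS
from .precision import AoacBands
from .simulate import AnalyteModel, StudyDesign, default_models

NOT_ASSESSED = "not assessed (missing data)"


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class ValidationConfig:
    """Everything the pipeline needs besides the measurements.

    ``models`` drive simulation only; validation itself is estimated purely
    from the data.  ``analytes`` optionally restricts the run to a subset —
    naming an analyte absent from the table is a configuration error.
    """

    models: dict[str, AnalyteModel] = field(default_factory=default_models)
    design: StudyDesign = field(default_factory=StudyDesign)
    analytes: tuple[str, ...] | None = None
    alpha: float = 0.05
    huber_band: float = 0.05
    bands: AoacBands = field(default_factory=AoacBands)


def default_config() -> ValidationConfig:
    return ValidationConfig()


# --------------------------------------------------------------------------
# report schema (pydantic = the bundled JSON-schema contract)
# --------------------------------------------------------------------------


class CalibrationBlock(BaseModel):
    status: str = "ok"
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    n_points: int | None = None
    residual_sd: float | None = None


class HuberBlock(BaseModel):
    target: float
    band_fraction: float
    factors_by_level: dict[str, float]
    pass_by_level: dict[str, bool]
    passed: bool


class LackOfFitBlock(BaseModel):
    ms_lack_of_fit: float
    ms_pure_error: float
    f_ratio: float
    df_lof: int
    df_pe: int
    f_critical: float
    passed: bool


class LinearityBlock(BaseModel):
    status: str = "ok"
    huber: HuberBlock | None = None
    lack_of_fit: LackOfFitBlock | None = None


class SensitivityBlock(BaseModel):
    status: str = "ok"
    y_blank_mean: float | None = None
    s_blank: float | None = None
    n_blanks: int | None = None
    lod: float | None = None
    loq: float | None = None
    printed: dict[str, float] | None = None


class MatrixEffectBlock(BaseModel):
    status: str = "ok"
    me_percent: float | None = None
    classification: str | None = None
    printed: dict[str, float] | None = None


class PrecisionRow(BaseModel):
    level: float
    s_w: float
    s_b: float
    s_b_component: float
    s_ip: float
    rsd_ip_percent: float
    mean_measured: float
    recovery_percent: float
    n_days: int
    replicates_per_day: int
    rsd_pass: bool
    recovery_pass: bool
    printed: dict[str, float]


class PrecisionBlock(BaseModel):
    status: str = "ok"
    rows: list[PrecisionRow] = []


class RobustnessFactor(BaseModel):
    factor: str
    effect: float
    t_value: float
    df: int
    t_critical: float
    robust: bool


class RobustnessBlock(BaseModel):
    status: str = "ok"
    s_precision: float | None = None
    df: int | None = None
    factors: list[RobustnessFactor] = []
    robust: bool | None = None


class AnalyteBlock(BaseModel):
    calibration: CalibrationBlock
    solvent_calibration: CalibrationBlock
    linearity: LinearityBlock
    sensitivity: SensitivityBlock
    matrix_effect: MatrixEffectBlock
    precision_recovery: PrecisionBlock
    robustness: RobustnessBlock
    verdicts: dict[str, bool | None]


class Provenance(BaseModel):
    package: str = "cyanoval"
    config_sha256: str
    input_sha256: str
    n_records: int
    seed: int | None = None


class ValidationReport(BaseModel):
    """The bundled report contract; ``model_json_schema()`` is its JSON schema."""

    analytes: dict[str, AnalyteBlock]
    provenance: Provenance


def _p2(x: float) -> float:
    return float(round(x, 2))


# --------------------------------------------------------------------------
# the model object
# --------------------------------------------------------------------------


class MethodValidation:
    """Validation protocol applied to a measurement table.

    Parameters
    ----------
    data
        Measurement DataFrame with the :data:`cyanoval.io.MEASUREMENT_COLUMNS`
        schema (see :func:`cyanoval.io.read_measurements`).
    config
        Optional :class:`ValidationConfig`; defaults reproduce the reference
        study design.
    """

    def __init__(self, data: pd.DataFrame, config: ValidationConfig | None = None):
        if data is None or len(data) == 0:
            raise CyanovalError("empty measurement table")
        missing = set(MEASUREMENT_COLUMNS) - set(data.columns)
        if missing:
            raise CyanovalError(f"measurement table missing columns: {sorted(missing)}")
        self.data = data
        self.config = config or default_config()
        present = set(data["analyte_id"].unique())
        if self.config.analytes is not None:
            unknown = set(self.config.analytes) - present
            if unknown:
                raise ConfigError(
                    f"configured analytes not present in data: {sorted(unknown)}"
                )
            self.analytes = tuple(self.config.analytes)
        else:
            self.analytes = tuple(sorted(present))

    @classmethod
    def from_csv(cls, path, config: ValidationConfig | None = None) -> "MethodValidation":
        from .io import read_measurements

        return cls(read_measurements(path), config)

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int | None = None) -> "ValidationResults":
        blocks: dict[str, AnalyteBlock] = {}
        for analyte in self.analytes:
            sub = self.data[self.data["analyte_id"] == analyte]
            blocks[analyte] = self._fit_analyte(analyte, sub)
        report = ValidationReport(
            analytes=blocks,
            provenance=Provenance(
                config_sha256=_config_digest(self.config),
                input_sha256=_table_digest(self.data),
                n_records=int(len(self.data)),
                seed=seed,
            ),
        )
        return ValidationResults(report)

    def _fit_analyte(self, analyte: str, sub: pd.DataFrame) -> AnalyteBlock:
        cfg = self.config
        by_type = {t: sub[sub["sample_type"] == t] for t in sub["sample_type"].unique()}
        matrix_std = by_type.get("matrix_std", sub.iloc[0:0])
        solvent_std = by_type.get("solvent_std", sub.iloc[0:0])
        blanks = by_type.get("blank", sub.iloc[0:0])
        spikes = by_type.get("spike", sub.iloc[0:0])
        youden = by_type.get("youden", sub.iloc[0:0])

        # calibration + linearity
        matrix_curve = None
        if len(matrix_std) >= 3:
            matrix_curve = cal.fit_calibration(matrix_std, analyte)
            cal_block = CalibrationBlock(
                slope=matrix_curve.slope,
                intercept=matrix_curve.intercept,
                r_squared=matrix_curve.r_squared,
                n_points=matrix_curve.n_points,
                residual_sd=matrix_curve.residual_sd,
            )
            huber = cal.huber_linearity(matrix_std, cfg.huber_band)
            lof = cal.lack_of_fit_anova(matrix_std, cfg.alpha)
            lin_block = LinearityBlock(
                huber=HuberBlock(
                    target=huber.target,
                    band_fraction=huber.band_fraction,
                    factors_by_level={str(k): v for k, v in huber.factors_by_level.items()},
                    pass_by_level={str(k): v for k, v in huber.pass_by_level.items()},
                    passed=huber.passed,
                ),
                lack_of_fit=LackOfFitBlock(
                    ms_lack_of_fit=lof.ms_lack_of_fit,
                    ms_pure_error=lof.ms_pure_error,
                    f_ratio=lof.f_ratio,
                    df_lof=lof.df_lof,
                    df_pe=lof.df_pe,
                    f_critical=lof.f_critical,
                    passed=lof.passed,
                ),
            )
        else:
            cal_block = CalibrationBlock(status=NOT_ASSESSED)
            lin_block = LinearityBlock(status=NOT_ASSESSED)

        # solvent calibration + matrix effect
        if len(solvent_std) >= 3:
            solvent_curve = cal.fit_calibration(solvent_std, analyte)
            solv_block = CalibrationBlock(
                slope=solvent_curve.slope,
                intercept=solvent_curve.intercept,
                r_squared=solvent_curve.r_squared,
                n_points=solvent_curve.n_points,
                residual_sd=solvent_curve.residual_sd,
            )
        else:
            solvent_curve = None
            solv_block = CalibrationBlock(status=NOT_ASSESSED)
        if solvent_curve is not None and matrix_curve is not None:
            me = sens.matrix_effect(solvent_curve, matrix_curve)
            me_block = MatrixEffectBlock(
                me_percent=me.me_percent,
                classification=me.classification,
                printed={"me_percent": _p2(me.me_percent)},
            )
        else:
            me_block = MatrixEffectBlock(status=NOT_ASSESSED)

        # sensitivity
        if len(blanks) >= 2 and matrix_curve is not None:
            bs = sens.blank_stats(blanks)
            dl = sens.detection_limits(bs, matrix_curve)
            sens_block = SensitivityBlock(
                y_blank_mean=bs.y_blank_mean,
                s_blank=bs.s_blank,
                n_blanks=bs.n_blanks,
                lod=dl.lod,
                loq=dl.loq,
                printed={"lod": _p2(dl.lod), "loq": _p2(dl.loq)},
            )
        else:
            sens_block = SensitivityBlock(status=NOT_ASSESSED)

        # precision / recovery
        rows: list[PrecisionRow] = []
        if len(spikes) > 0 and matrix_curve is not None:
            for level, grp in spikes.groupby("nominal_conc"):
                conc = matrix_curve.inverse(grp["response"].to_numpy())
                frame = pd.DataFrame({"day": grp["day"].to_numpy(), "concentration": conc})
                est = prec.precision_study(frame, float(level), analyte)
                rec = prec.recovery(est.mean_measured, float(level), cfg.bands, analyte)
                rows.append(
                    PrecisionRow(
                        level=float(level),
                        s_w=est.s_w,
                        s_b=est.s_b_paper,
                        s_b_component=est.s_b_component,
                        s_ip=est.s_ip,
                        rsd_ip_percent=est.rsd_ip_percent,
                        mean_measured=est.mean_measured,
                        recovery_percent=rec.recovery_percent,
                        n_days=est.n_days,
                        replicates_per_day=est.replicates_per_day,
                        rsd_pass=prec.assess_precision(est, cfg.bands),
                        recovery_pass=rec.passed,
                        printed={
                            "s_w": _p2(est.s_w),
                            "s_b": _p2(est.s_b_paper),
                            "s_ip": _p2(est.s_ip),
                            "rsd_ip_percent": _p2(est.rsd_ip_percent),
                            "recovery_percent": _p2(rec.recovery_percent),
                        },
                    )
                )
            prec_block = PrecisionBlock(rows=rows)
        else:
            prec_block = PrecisionBlock(status=NOT_ASSESSED)

        # robustness: error SD = sample SD of the precision measurements at
        # the Youden spike level (df = n - 1)
        level = cfg.design.youden_level
        spikes_at_level = spikes[spikes["nominal_conc"] == level]
        if len(youden) > 0 and matrix_curve is not None and len(spikes_at_level) >= 3:
            conc_prec = matrix_curve.inverse(spikes_at_level["response"].to_numpy())
            s_precision = float(np.std(conc_prec, ddof=1))
            df = int(len(conc_prec) - 1)
            conc_y = matrix_curve.inverse(youden["response"].to_numpy())
            results = pd.DataFrame(
                {"combo": youden["youden_combo"].to_numpy(), "concentration": conc_y}
            )
            analysis = rob.youden_analysis(results, s_precision, df, cfg.alpha)
            factors = [
                RobustnessFactor(
                    factor=f,
                    effect=e.effect,
                    t_value=e.t_value,
                    df=e.df,
                    t_critical=e.t_critical,
                    robust=e.robust,
                )
                for f, e in analysis.items()
            ]
            rob_block = RobustnessBlock(
                s_precision=s_precision,
                df=df,
                factors=factors,
                robust=all(f.robust for f in factors),
            )
        else:
            rob_block = RobustnessBlock(status=NOT_ASSESSED)

        verdicts: dict[str, bool | None] = {
            "linearity": (
                lin_block.huber.passed and lin_block.lack_of_fit.passed
                if lin_block.status == "ok"
                else None
            ),
            "precision": (
                all(r.rsd_pass for r in rows) if prec_block.status == "ok" else None
            ),
            "recovery": (
                all(r.recovery_pass for r in rows) if prec_block.status == "ok" else None
            ),
            "robustness": rob_block.robust if rob_block.status == "ok" else None,
        }
        return AnalyteBlock(
            calibration=cal_block,
            solvent_calibration=solv_block,
            linearity=lin_block,
            sensitivity=sens_block,
            matrix_effect=me_block,
            precision_recovery=prec_block,
            robustness=rob_block,
            verdicts=verdicts,
        )


def run_validation(
    measurements: pd.DataFrame, config: ValidationConfig | None = None
) -> "ValidationResults":
    """Functional entry point: validate a measurement table end to end."""
    return MethodValidation(measurements, config).fit()


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------


class ValidationResults:
    """Container for a fitted validation: report access, JSON, summary."""

    def __init__(self, report: ValidationReport):
        self.report = report

    def to_dict(self) -> dict:
        return self.report.model_dump()

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ValidationResults":
        with open(path, encoding="utf-8") as fh:
            return cls(ValidationReport.model_validate(json.load(fh)))

    def summary(self) -> str:
        """Text report mirroring the conventional validation-table layout."""
        lines: list[str] = []
        w = lines.append
        w("Method validation summary")
        w("=" * 78)
        hdr = (
            f"{'analyte':8s} {'level':>6s} {'S_w':>7s} {'S_B':>7s} {'S_IP':>7s} "
            f"{'%RSD_IP':>8s} {'rec%':>7s} {'LOD':>6s} {'LOQ':>6s}"
        )
        w(hdr)
        w("-" * 78)
        for analyte, blk in self.report.analytes.items():
            sens_p = blk.sensitivity
            lod = f"{sens_p.lod:.2f}" if sens_p.status == "ok" else "-"
            loq = f"{sens_p.loq:.2f}" if sens_p.status == "ok" else "-"
            if blk.precision_recovery.status == "ok":
                for i, r in enumerate(blk.precision_recovery.rows):
                    w(
                        f"{analyte if i == 0 else '':8s} {r.level:6.0f} "
                        f"{r.s_w:7.2f} {r.s_b:7.2f} {r.s_ip:7.2f} "
                        f"{r.rsd_ip_percent:8.2f} {r.recovery_percent:7.2f} "
                        f"{lod if i == 0 else '-':>6s} {loq if i == 0 else '-':>6s}"
                    )
            else:
                w(f"{analyte:8s}  precision/recovery: {blk.precision_recovery.status}")
        w("-" * 78)
        for analyte, blk in self.report.analytes.items():
            c = blk.calibration
            if c.status == "ok":
                w(
                    f"{analyte:8s} calibration: y = {c.slope:.4g} x + {c.intercept:.4g} "
                    f"(r2 = {c.r_squared:.4f}, n = {c.n_points})"
                )
            me = blk.matrix_effect
            if me.status == "ok":
                w(
                    f"{analyte:8s} matrix effect: {me.me_percent:+.2f}% "
                    f"({me.classification})"
                )
            rb = blk.robustness
            if rb.status == "ok":
                ts = ", ".join(f"{f.factor}: t={f.t_value:.3f}" for f in rb.factors)
                w(
                    f"{analyte:8s} robustness (t_crit={rb.factors[0].t_critical:.3f}, "
                    f"df={rb.df}): {ts} -> "
                    f"{'robust' if rb.robust else 'NOT robust'}"
                )
            w(
                f"{analyte:8s} verdicts: "
                + ", ".join(
                    f"{k}={'pass' if v else 'FAIL' if v is not None else 'n/a'}"
                    for k, v in blk.verdicts.items()
                )
            )
        return "\n".join(lines)


# --------------------------------------------------------------------------
# provenance digests
# --------------------------------------------------------------------------


def _table_digest(df: pd.DataFrame) -> str:
    payload = df.loc[:, list(MEASUREMENT_COLUMNS)].to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


def _config_digest(config: ValidationConfig) -> str:
    from .config import config_to_mapping

    payload = json.dumps(config_to_mapping(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
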