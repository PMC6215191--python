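"""YAML configuration mirroring the generator models and study design.

The file has up to four top-level keys, all optional (defaults reproduce
the reference study)::

    design:
      calibration_levels: [0.2, 0.5, ...]
      days: 3
      ...
    analytes:
      MC-LR:
        slope: 127.47
        intercept: 1.0247
        matrix_slope_ratio: 1.0423
        recovery_fraction_by_level: {5: 0.609, 20: 0.799, 50: 0.84}
        within_day_sd_by_level: {5: 0.2, 20: 2.06, 50: 4.62}
        day_effect_sd_by_level: {5: 0.62, 20: 0.45, 50: 4.35}
        blank_mean: 3.30
        blank_sd: 1.90
    options:
      alpha: 0.05
      huber_band: 0.05
      analytes: [MC-LR, CYN]     # restrict the run
    bands:
      rsd: {5: [16, 22], 20: [8, 16], 50: [8, 16]}
      recovery: {5: [40, 115], 20: [60, 110], 50: [60, 110]}
"""

from __future__ import annotations

from dataclasses import asdict, fields

import yaml

from .exceptions import ConfigError, CyanovalError
from .precision import AoacBands
from .simulate import AnalyteModel, StudyDesign
from .validation import ValidationConfig


def _float_keys(m) -> dict[float, float]:
    return {float(k): float(v) for k, v in m.items()}


def _build_model(analyte_id: str, entry: dict) -> AnalyteModel:
    known = {f.name for f in fields(AnalyteModel)} - {"analyte_id"}
    unknown = set(entry) - known
    if unknown:
        raise ConfigError(f"{analyte_id}: unknown model keys {sorted(unknown)}")
    kwargs = dict(entry)
    for key in (
        "recovery_fraction_by_level",
        "within_day_sd_by_level",
        "day_effect_sd_by_level",
    ):
        if key in kwargs:
            kwargs[key] = _float_keys(kwargs[key])
        else:
            kwargs[key] = {}
    if "calibration_sd_by_level" in kwargs:
        kwargs["calibration_sd_by_level"] = _float_keys(kwargs["calibration_sd_by_level"])
    try:
        return AnalyteModel(analyte_id=analyte_id, **kwargs)
    except TypeError as exc:
        raise ConfigError(f"{analyte_id}: {exc}") from None


def load_config(path) -> ValidationConfig:
    """Read a YAML config; missing sections fall back to study defaults."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    cfg = ValidationConfig()
    if "design" in raw:
        known = {f.name for f in fields(StudyDesign)}
        unknown = set(raw["design"]) - known
        if unknown:
            raise ConfigError(f"unknown design keys {sorted(unknown)}")
        d = dict(raw["design"])
        for key in ("calibration_levels", "validation_levels"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        try:
            cfg.design = StudyDesign(**d)
        except CyanovalError:
            raise
    if "analytes" in raw:
        cfg.models = {
            name: _build_model(name, entry or {}) for name, entry in raw["analytes"].items()
        }
    opts = raw.get("options", {})
    if "alpha" in opts:
        cfg.alpha = float(opts["alpha"])
    if "huber_band" in opts:
        cfg.huber_band = float(opts["huber_band"])
    if "analytes" in opts:
        cfg.analytes = tuple(opts["analytes"])
    if "bands" in raw:
        b = raw["bands"]
        cfg.bands = AoacBands(
            rsd={float(k): tuple(map(float, v)) for k, v in b.get("rsd", {}).items()}
            or AoacBands().rsd,
            recovery={
                float(k): tuple(map(float, v)) for k, v in b.get("recovery", {}).items()
            }
            or AoacBands().recovery,
        )
    return cfg


def config_to_mapping(cfg: ValidationConfig) -> dict:
    """Plain-dict form of a config (for YAML dump and hashing)."""
    analytes = {}
    for name, m in sorted(cfg.models.items()):
        d = asdict(m)
        d.pop("analyte_id")
        for key in (
            "recovery_fraction_by_level",
            "within_day_sd_by_level",
            "day_effect_sd_by_level",
            "calibration_sd_by_level",
        ):
            d[key] = {float(k): float(v) for k, v in d[key].items()}
        analytes[name] = d
    out = {
        "design": {
            **asdict(cfg.design),
            "calibration_levels": list(cfg.design.calibration_levels),
            "validation_levels": list(cfg.design.validation_levels),
        },
        "analytes": analytes,
        "options": {"alpha": cfg.alpha, "huber_band": cfg.huber_band},
        "bands": {
            "rsd": {k: list(v) for k, v in cfg.bands.rsd.items()},
            "recovery": {k: list(v) for k, v in cfg.bands.recovery.items()},
        },
    }
    if cfg.analytes is not None:
        out["options"]["analytes"] = list(cfg.analytes)
    return out


def dump_config(cfg: ValidationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_mapping(cfg), fh, sort_keys=True)
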