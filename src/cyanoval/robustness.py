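"""Youden ruggedness assessment on a full 2**3 factorial.

The robustness of a sample-preparation procedure is screened by deliberately
varying three procedure parameters between a high (+) and a low (-) setting:

* F1 - sonication time of the extract,
* F2 - orbital-stirring time,
* F3 - time for the sample to pass through the SPE cartridge train,

running the eight possible combinations C1..C8 at a single mid-range spike
level, and computing for each factor the effect

    D_F = mean(concentration | F at +) - mean(concentration | F at -)

over the four runs on each side.  The effect is referred to a Student t
statistic using an externally supplied precision standard deviation (the
SD of the intermediate-precision study at the same level), and the method
is declared robust to a factor when |t| stays below the two-tailed critical
value at that SD's degrees of freedom.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CyanovalError, DesignError

FACTORS = ("F1", "F2", "F3")

FACTOR_NAMES = {
    "F1": "sonication time",
    "F2": "stirring time",
    "F3": "cartridge-pass time",
}

#: high/low settings of each factor, as displayed in run sheets
FACTOR_LEVEL_VALUES = {
    "F1": {"+": "15 min", "-": "10 min"},
    "F2": {"+": "15 min", "-": "10 min"},
    "F3": {"+": "1 min", "-": "1 min 15 s"},
}

#: the eight combinations, C1 = (+,+,+) ... C8 = (-,-,-)
COMBINATION_SIGNS = {
    "C1": ("+", "+", "+"),
    "C2": ("+", "+", "-"),
    "C3": ("+", "-", "+"),
    "C4": ("+", "-", "-"),
    "C5": ("-", "+", "+"),
    "C6": ("-", "+", "-"),
    "C7": ("-", "-", "+"),
    "C8": ("-", "-", "-"),
}


@dataclass(frozen=True)
class YoudenDesign:
    """The 2**3 combination table used for the ruggedness runs."""

    factors: tuple[str, ...] = FACTORS
    level_values: Mapping[str, Mapping[str, str]] = field(
        default_factory=lambda: dict(FACTOR_LEVEL_VALUES)
    )
    combinations: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(COMBINATION_SIGNS)
    )

    def sign(self, combo: str, factor: str) -> int:
        """Return +1/-1 for ``factor`` in ``combo``."""
        return 1 if self.combinations[combo][self.factors.index(factor)] == "+" else -1

    def setting(self, combo: str, factor: str) -> str:
        """Human-readable setting (e.g. ``'15 min'``) of a factor in a combo."""
        s = self.combinations[combo][self.factors.index(factor)]
        return self.level_values[factor][s]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"combo": c, **{f: self.setting(c, f) for f in self.factors}}
            for c in self.combinations
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FactorEffect:
    """Effect of one procedure factor with its significance verdict."""

    factor: str
    effect: float  # D, ug/L: mean at + minus mean at -
    t_value: float
    df: int
    t_critical: float

    @property
    def robust(self) -> bool:
        return abs(self.t_value) < self.t_critical


def build_design() -> YoudenDesign:
    """Return the standard three-factor, eight-run combination table."""
    return YoudenDesign()


def factor_effects(
    results: Mapping[str, float] | pd.DataFrame,
    design: YoudenDesign | None = None,
) -> dict[str, float]:
    """Per-factor effects D = mean(+ runs) - mean(- runs).

    Parameters
    ----------
    results
        Measured concentrations keyed by combination label, either a mapping
        ``{"C1": conc, ...}`` or a DataFrame with ``combo`` and
        ``concentration`` columns.  Replicated combinations are averaged.
    """
    design = design or build_design()
    if isinstance(results, pd.DataFrame):
        grouped = results.groupby("combo")["concentration"].mean()
        results = grouped.to_dict()
    missing = sorted(set(design.combinations) - set(results))
    if missing:
        raise DesignError(f"incomplete Youden design: missing combinations {missing}")

    effects: dict[str, float] = {}
    for f in design.factors:
        plus = [results[c] for c in design.combinations if design.sign(c, f) > 0]
        minus = [results[c] for c in design.combinations if design.sign(c, f) < 0]
        effects[f] = float(np.mean(plus) - np.mean(minus))
    return effects


def youden_t(effect: float, s_precision: float, n_per_side: int = 4) -> float:
    """t statistic for a factor effect.

    The effect D is a difference of two means of ``n_per_side`` runs each, so
    SE(D) = s * sqrt(2 / n_per_side) with ``s_precision`` the precision SD of
    the method at the robustness spike level.
    """
    if s_precision <= 0:
        raise CyanovalError("s_precision must be > 0")
    return abs(effect) / (s_precision * np.sqrt(2.0 / n_per_side))


def t_critical(df: int, alpha: float = 0.05) -> float:
    """Two-tailed Student t critical value (2.306 at 8 df, alpha 0.05)."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def assess_robustness(
    effects: Mapping[str, FactorEffect] | Mapping[str, float],
    t_crit: float | None = None,
) -> dict[str, bool]:
    """Per-factor robustness verdicts: robust iff |t| < critical value.

    Accepts either a mapping of :class:`FactorEffect` (each carrying its own
    critical value) or a mapping of raw t values together with ``t_crit``.
    An empty mapping is an error — robustness cannot pass vacuously.
    """
    if not effects:
        raise CyanovalError("no factor effects supplied; cannot assess robustness")
    verdicts: dict[str, bool] = {}
    for factor, e in effects.items():
        if isinstance(e, FactorEffect):
            verdicts[factor] = e.robust
        else:
            if t_crit is None:
                raise CyanovalError("t_crit required when passing raw t values")
            verdicts[factor] = abs(float(e)) < t_crit
    return verdicts


def youden_analysis(
    results: Mapping[str, float] | pd.DataFrame,
    s_precision: float,
    df: int,
    alpha: float = 0.05,
    design: YoudenDesign | None = None,
) -> dict[str, FactorEffect]:
    """Full per-factor analysis: effects, t statistics and verdicts."""
    design = design or build_design()
    effects = factor_effects(results, design)
    tc = t_critical(df, alpha)
    return {
        f: FactorEffect(
            factor=f,
            effect=d,
            t_value=youden_t(d, s_precision),
            df=df,
            t_critical=tc,
        )
        for f, d in effects.items()
    }
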