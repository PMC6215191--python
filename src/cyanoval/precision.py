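"""Precision variance components, recovery, and AOAC acceptance bands.

A balanced one-way ANOVA with day as the random factor decomposes the
back-calculated concentrations of a spiked-sample study (D days x r
replicates per day at one level) into a within-day mean square MS_w and a
between-day mean square MS_b.  The quantities reported are

* repeatability          S_w  = sqrt(MS_w)
* between-day spread     S_B  = sqrt(MS_b)            (the reported value)
* day variance component sigma_day = sqrt(max(0, (MS_b - MS_w) / r))
* intermediate precision S_IP = sqrt(MS_w + max(0, (MS_b - MS_w) / r))
* %RSD_IP = 100 * S_IP / mean measured concentration

Note S_B is the square root of the between-day *mean square*, not of the
day variance component; both are exposed.  Recovery is the grand mean of
the measured concentrations over the spiked "true" value T, in percent.
Both %RSD_IP and recovery are judged against the AOAC single-laboratory
acceptance bands for the spike level.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import CyanovalError, DesignError


class DayAnova(NamedTuple):
    """Balanced one-way ANOVA summary with day as the grouping factor."""

    ms_within: float
    ms_between: float
    df_within: int
    df_between: int
    grand_mean: float
    n_days: int
    replicates_per_day: int


@dataclass(frozen=True)
class PrecisionEstimates:
    """Per analyte x level precision summary."""

    analyte_id: str
    level: float
    s_w: float
    s_b_paper: float  # sqrt(MS_between), the conventionally reported S_B
    s_b_component: float  # sqrt of the day variance component
    s_ip: float
    rsd_ip_percent: float
    mean_measured: float
    n_days: int
    replicates_per_day: int


@dataclass(frozen=True)
class RecoveryResult:
    analyte_id: str
    level: float
    recovery_percent: float
    passed: bool


@dataclass(frozen=True)
class AoacBands:
    """AOAC single-laboratory acceptance bands by spike level (ug/L).

    ``rsd`` maps level -> (low, high) %RSD band; only the upper bound is
    binding for a pass.  ``recovery`` maps level -> (low, high) percent.
    Extensible via config for levels outside the default design.
    """

    rsd: Mapping[float, tuple[float, float]] = field(
        default_factory=lambda: {5.0: (16.0, 22.0), 20.0: (8.0, 16.0), 50.0: (8.0, 16.0)}
    )
    recovery: Mapping[float, tuple[float, float]] = field(
        default_factory=lambda: {5.0: (40.0, 115.0), 20.0: (60.0, 110.0), 50.0: (60.0, 110.0)}
    )

    def rsd_upper(self, level: float) -> float:
        try:
            return self.rsd[level][1]
        except KeyError:
            raise CyanovalError(f"no AOAC RSD band configured for level {level}") from None

    def recovery_band(self, level: float) -> tuple[float, float]:
        try:
            return self.recovery[level]
        except KeyError:
            raise CyanovalError(
                f"no AOAC recovery band configured for level {level}"
            ) from None


def anova_by_day(groups) -> DayAnova:
    """Balanced one-way ANOVA over days.

    ``groups`` is either a mapping day -> sequence of measured
    concentrations, or a DataFrame with ``day`` and ``concentration``
    columns.  The layout must be balanced (equal replicates per day);
    unbalanced data are rejected because the component formulas assume
    balance.
    """
    if isinstance(groups, pd.DataFrame):
        groups = {d: g["concentration"].to_numpy() for d, g in groups.groupby("day")}
    arrays = {d: np.asarray(v, dtype=float) for d, v in groups.items()}
    if len(arrays) < 2:
        raise DesignError("need >= 2 days")
    sizes = {a.size for a in arrays.values()}
    if len(sizes) != 1:
        raise DesignError("unbalanced design: unequal replicates per day")
    r = sizes.pop()
    if r < 2:
        raise DesignError("need >= 2 replicates per day")
    d = len(arrays)
    data = np.stack([arrays[k] for k in sorted(arrays)])
    day_means = data.mean(axis=1)
    grand = float(data.mean())
    ss_between = r * float(np.sum((day_means - grand) ** 2))
    ss_within = float(np.sum((data - day_means[:, None]) ** 2))
    df_b, df_w = d - 1, d * (r - 1)
    return DayAnova(
        ms_within=ss_within / df_w,
        ms_between=ss_between / df_b,
        df_within=df_w,
        df_between=df_b,
        grand_mean=grand,
        n_days=d,
        replicates_per_day=r,
    )


def intermediate_precision_sd(s_w: float, s_b: float, r: int) -> float:
    """S_IP from the reported S_w and S_B (= sqrt of the mean squares).

    S_IP = sqrt(S_w^2 + max(0, (S_B^2 - S_w^2) / r)) for a balanced design
    with r replicates per day; the day component is truncated at zero when
    MS_between <= MS_within.
    """
    if s_w < 0 or s_b < 0:
        raise CyanovalError("standard deviations must be >= 0")
    if r < 2:
        raise DesignError("need r >= 2 replicates per day")
    return math.sqrt(s_w**2 + max(0.0, (s_b**2 - s_w**2) / r))


def precision_components(
    ms_within: float,
    ms_between: float,
    r: int,
) -> tuple[float, float, float, float]:
    """(s_w, s_b_paper, s_b_component, s_ip) from the two mean squares."""
    if ms_within < 0 or ms_between < 0:
        raise CyanovalError("mean squares must be >= 0")
    if r < 2:
        raise DesignError("need r >= 2 replicates per day")
    s_w = math.sqrt(ms_within)
    s_b_paper = math.sqrt(ms_between)
    comp = max(0.0, (ms_between - ms_within) / r)
    return s_w, s_b_paper, math.sqrt(comp), math.sqrt(ms_within + comp)


def rsd_ip(s_ip: float, mean_measured: float) -> float:
    """%RSD_IP = 100 * S_IP / mean measured concentration."""
    if mean_measured <= 0:
        raise CyanovalError("mean measured concentration must be > 0")
    return 100.0 * s_ip / mean_measured


def recovery(
    mean_measured: float,
    level: float,
    bands: AoacBands | None = None,
    analyte_id: str = "",
) -> RecoveryResult:
    """Recovery% = 100 * mean measured / T, judged against the AOAC band."""
    if level <= 0:
        raise CyanovalError("spike level T must be > 0")
    bands = bands or AoacBands()
    pct = 100.0 * mean_measured / level
    lo, hi = bands.recovery_band(level)
    return RecoveryResult(
        analyte_id=analyte_id, level=level, recovery_percent=pct, passed=lo <= pct <= hi
    )


def assess_precision(estimates: PrecisionEstimates, bands: AoacBands | None = None) -> bool:
    """Pass iff %RSD_IP <= the upper AOAC bound at that level."""
    bands = bands or AoacBands()
    return estimates.rsd_ip_percent <= bands.rsd_upper(estimates.level)


def precision_study(
    concentrations_by_day,
    level: float,
    analyte_id: str = "",
) -> PrecisionEstimates:
    """End-to-end precision estimation for one analyte x level.

    Runs the balanced one-way ANOVA and assembles all reported quantities.
    """
    a = anova_by_day(concentrations_by_day)
    s_w, s_b_paper, s_b_comp, s_ip = precision_components(
        a.ms_within, a.ms_between, a.replicates_per_day
    )
    return PrecisionEstimates(
        analyte_id=analyte_id,
        level=level,
        s_w=s_w,
        s_b_paper=s_b_paper,
        s_b_component=s_b_comp,
        s_ip=s_ip,
        rsd_ip_percent=rsd_ip(s_ip, a.grand_mean),
        mean_measured=a.grand_mean,
        n_days=a.n_days,
        replicates_per_day=a.replicates_per_day,
    )
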