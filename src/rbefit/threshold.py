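"""One-way ANOVA with Bonferroni dose-vs-control tests and threshold dose.

The experiment compares rosette counts across dose groups.  The ANOVA is
computed from the group summaries (mean, SD, n) — algebraically identical
to the raw per-embryo ANOVA whenever the summaries came from raw counts:

    SS_between = sum n_i (m_i - mbar)^2     (mbar the n-weighted grand mean)
    SS_within  = sum (n_i - 1) s_i^2
    F = [SS_between / (k-1)] / [SS_within / (N-k)]

Each non-control dose is then compared with the control using the pooled
mean-square error,

    t_i = (m_i - m_0) / sqrt(MSE (1/n_i + 1/n_0)),   df = N - k,

with two-sided p-values multiplied by the number of comparisons
(Bonferroni, capped at 1).  Significance is flagged at 0.05 (significant)
and 0.01 (highly significant).

The threshold dose interval is (highest non-significant dose, lowest
significant dose): the no-effect/effect boundary the design can resolve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .data import DoseGroup, DoseResponseDataset
from .exceptions import DataValidationError, DegenerateVarianceError

__all__ = [
    "AnovaResult",
    "Comparison",
    "ThresholdReport",
    "anova_from_summary",
    "pairwise_bonferroni_vs_control",
    "threshold_interval",
    "threshold_report",
]


class AnovaResult(NamedTuple):
    F: float
    df_between: int
    df_within: int
    p_overall: float
    mse: float


class Comparison(NamedTuple):
    """One dose-vs-control contrast with its Bonferroni-adjusted p-value."""

    dose: float
    t: float
    p_raw: float
    p_adjusted: float
    significant_05: bool
    significant_01: bool


class ThresholdInterval(NamedTuple):
    low: Optional[float]
    high: Optional[float]
    monotone: bool


def anova_from_summary(groups: Sequence[DoseGroup]) -> AnovaResult:
    """One-way ANOVA from per-group (mean, sd, n) summaries."""
    if len(groups) < 2:
        raise DataValidationError("ANOVA needs at least 2 groups")
    m = np.array([g.mean for g in groups])
    s = np.array([g.sd for g in groups])
    n = np.array([g.n for g in groups], dtype=float)
    k = len(groups)
    N = n.sum()
    if N <= k:
        raise DataValidationError("total N must exceed the number of groups")
    grand = (n * m).sum() / N
    ss_between = float((n * (m - grand) ** 2).sum())
    ss_within = float(((n - 1) * s**2).sum())
    df_between, df_within = k - 1, int(N - k)
    if ss_within <= 0:
        raise DegenerateVarianceError(
            "pooled within-group variance is zero; ANOVA is undefined"
        )
    mse = ss_within / df_within
    F = (ss_between / df_between) / mse
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(F=F, df_between=df_between, df_within=df_within, p_overall=p, mse=mse)


def pairwise_bonferroni_vs_control(
    groups: Sequence[DoseGroup], control_dose: float = 0.0
) -> list[Comparison]:
    """Pooled-MSE t tests of every non-control group against the control,
    Bonferroni-adjusted over the number of non-control groups."""
    control = [g for g in groups if g.dose == control_dose]
    if not control:
        raise DataValidationError(f"no control group at dose {control_dose} Gy")
    others = [g for g in groups if g.dose != control_dose]
    if not others:
        raise DataValidationError("need at least one non-control group")
    anova = anova_from_summary(groups)
    g0 = control[0]
    n_comp = len(others)
    out = []
    for g in sorted(others, key=lambda g: g.dose):
        se = np.sqrt(anova.mse * (1.0 / g.n + 1.0 / g0.n))
        t = (g.mean - g0.mean) / se
        p_raw = float(2.0 * stats.t.sf(abs(t), anova.df_within))
        p_adj = min(1.0, p_raw * n_comp)
        out.append(
            Comparison(
                dose=g.dose,
                t=float(t),
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant_05=p_adj < 0.05,
                significant_01=p_adj < 0.01,
            )
        )
    return out


def threshold_interval(
    comparisons: Sequence[Comparison], level: float = 0.01
) -> ThresholdInterval:
    """Bracket the threshold dose from sorted dose-vs-control comparisons.

    ``high`` is the lowest significant dose at ``level``; ``low`` the
    highest non-significant dose below it (0 when every dose is
    significant).  Both are None when nothing is significant.  A
    non-significant dose above a significant one makes the pattern
    non-monotone; it is reported with ``monotone=False`` instead of
    raising.
    """
    if level not in (0.05, 0.01):
        raise DataValidationError("level must be 0.05 or 0.01")
    comps = sorted(comparisons, key=lambda c: c.dose)
    flag = "significant_01" if level == 0.01 else "significant_05"
    sig = [getattr(c, flag) for c in comps]
    if not any(sig):
        return ThresholdInterval(low=None, high=None, monotone=True)
    first = sig.index(True)
    monotone = all(sig[first:])
    high = comps[first].dose
    low = comps[first - 1].dose if first > 0 else 0.0
    return ThresholdInterval(low=low, high=high, monotone=monotone)


@dataclass(frozen=True)
class ThresholdReport:
    """Full ANOVA + Bonferroni + threshold-interval report for one dataset."""

    anova: AnovaResult
    comparisons: tuple[Comparison, ...]
    level: float
    threshold_low: Optional[float]
    threshold_high: Optional[float]
    monotone: bool

    def to_dict(self) -> dict:
        return {
            "anova": {
                "F": self.anova.F,
                "df_between": self.anova.df_between,
                "df_within": self.anova.df_within,
                "p_overall": self.anova.p_overall,
                "mse": self.anova.mse,
            },
            "comparisons": [c._asdict() for c in self.comparisons],
            "level": self.level,
            "threshold_low_gy": self.threshold_low,
            "threshold_high_gy": self.threshold_high,
            "monotone_significance": self.monotone,
        }


def threshold_report(
    ds: DoseResponseDataset, control_dose: float = 0.0, level: float = 0.01
) -> ThresholdReport:
    """Run the full pipeline on a dataset: ANOVA, dose-vs-control
    Bonferroni tests, and the threshold interval at ``level``."""
    anova = anova_from_summary(ds.groups)
    comps = pairwise_bonferroni_vs_control(ds.groups, control_dose=control_dose)
    interval = threshold_interval(comps, level=level)
    return ThresholdReport(
        anova=anova,
        comparisons=tuple(comps),
        level=level,
        threshold_low=interval.low,
        threshold_high=interval.high,
        monotone=interval.monotone,
    )
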