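"""Method-comparison statistics per food group.

For each food group the two indicator streams (questionnaire vs. recall
reference) are cross-tabulated over matched respondent-days:

=====================  ====================  ====================
                       recall negative       recall positive
=====================  ====================  ====================
questionnaire negative a (true negative)     c (false negative, type II)
questionnaire positive b (false positive,    d (true positive)
                       type I)
=====================  ====================  ====================

The percentage agreement coefficient is ((a+d)/n)*100.  Misreporting
percentages are taken over *all* observations (b/n, c/n), which makes
agreement + FP% + FN% identically 100.  Sensitivity d/(c+d) and
specificity a/(a+b) treat the recall as the reference method; a zero
denominator yields NaN (not available) rather than a fabricated rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .groups import GROUPS, FoodGroup
from .scoring import IndicatorSet

__all__ = [
    "TwoByTwo",
    "AgreementStats",
    "PrevalenceComparison",
    "crosstab",
    "agreement_coefficient",
    "sensitivity_specificity",
    "misreport_rates",
    "agreement_stats",
    "prevalence_comparison",
    "is_meaningful",
]

IndicatorInput = Union[pd.DataFrame, Sequence[IndicatorSet]]


@dataclass(frozen=True)
class TwoByTwo:
    """Agreement cross-tabulation counts for one food group."""

    a: int  # neither method positive
    b: int  # questionnaire positive, recall negative (type I)
    c: int  # questionnaire negative, recall positive (type II)
    d: int  # both positive

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AgreementStats:
    agreement_pct: float
    fp_pct: float
    fn_pct: float
    sensitivity: float  # NaN when c + d == 0
    specificity: float  # NaN when a + b == 0


@dataclass(frozen=True)
class PrevalenceComparison:
    group: FoodGroup
    p_dqq: float     # % positive by questionnaire
    p_r24h: float    # % positive by recall
    diff_pp: float   # p_dqq - p_r24h, percentage points
    p_value: float   # mixed-model test; NaN when degenerate
    meaningful: bool


def _as_frame(x: IndicatorInput) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x
    rows = {(s.respondent_id, s.day): s.as_tuple() for s in x}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[g.value for g in GROUPS])
    df.index = pd.MultiIndex.from_tuples(df.index, names=["respondent_id", "day"])
    return df.sort_index()


def match_indicator_frames(
    dqq: IndicatorInput, recall: IndicatorInput
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align the two methods on their common (respondent, day) observations."""
    dq, rc = _as_frame(dqq), _as_frame(recall)
    common = dq.index.intersection(rc.index).sort_values()
    if len(common) == 0:
        raise ValueError("no matched (respondent_id, day) observations between methods")
    return dq.loc[common], rc.loc[common]


def crosstab(dqq: IndicatorInput, recall: IndicatorInput, group: FoodGroup) -> TwoByTwo:
    """Cross-tabulate one group's flags over matched respondent-days."""
    dq, rc = match_indicator_frames(dqq, recall)
    x = dq[group.value].to_numpy().astype(bool)
    y = rc[group.value].to_numpy().astype(bool)
    return TwoByTwo(
        a=int(np.sum(~x & ~y)),
        b=int(np.sum(x & ~y)),
        c=int(np.sum(~x & y)),
        d=int(np.sum(x & y)),
    )


def agreement_coefficient(t: TwoByTwo) -> float:
    """Percentage agreement, ((a + d)/n) * 100."""
    if t.n == 0:
        raise ValueError("empty 2x2 table")
    return 100.0 * (t.a + t.d) / t.n


def misreport_rates(t: TwoByTwo) -> tuple[float, float]:
    """(false-positive %, false-negative %) over all n observations."""
    if t.n == 0:
        raise ValueError("empty 2x2 table")
    return 100.0 * t.b / t.n, 100.0 * t.c / t.n


def sensitivity_specificity(t: TwoByTwo) -> tuple[float, float]:
    """(d/(c+d), a/(a+b)) with the recall as reference; NaN when undefined."""
    if t.n == 0:
        raise ValueError("empty 2x2 table")
    sens = t.d / (t.c + t.d) if (t.c + t.d) > 0 else math.nan
    spec = t.a / (t.a + t.b) if (t.a + t.b) > 0 else math.nan
    return sens, spec


def agreement_stats(t: TwoByTwo) -> AgreementStats:
    fp, fn = misreport_rates(t)
    sens, spec = sensitivity_specificity(t)
    return AgreementStats(agreement_coefficient(t), fp, fn, sens, spec)


def is_meaningful(p_value: float, diff_pp: float,
                  alpha: float = 0.05, meaningful_pp: float = 10.0) -> bool:
    """Dual criterion: statistically significant AND >10 pp difference."""
    if not math.isfinite(p_value):
        return False
    return (p_value < alpha) and (abs(diff_pp) > meaningful_pp)


def _method_effect_pvalue(y: np.ndarray, method: np.ndarray,
                          respondents: np.ndarray) -> float:
    """Wald p for the method effect in a random-intercept linear model.

    A linear probability model on the stacked binary indicator with a
    respondent random intercept absorbs the dependence between the two
    recall days and the two methods of one person.
    """
    import statsmodels.api as sm

    if np.all(y == y[0]):
        return math.nan
    exog = np.column_stack([np.ones_like(method, dtype=float), method.astype(float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y.astype(float), exog, groups=respondents)
            try:
                res = model.fit(reml=True)
            except np.linalg.LinAlgError:
                res = model.fit(reml=True, method="powell")
            pv = float(res.pvalues[1])
        except (np.linalg.LinAlgError, ValueError):
            return math.nan
    return pv


def prevalence_comparison(
    dqq: IndicatorInput,
    recall: IndicatorInput,
    group: FoodGroup,
    alpha: float = 0.05,
    meaningful_pp: float = 10.0,
) -> PrevalenceComparison:
    """Questionnaire-vs-recall prevalence difference for one food group.

    The difference is questionnaire minus recall, in percentage points,
    tested with a random-intercept linear mixed model on the stacked
    indicator.  A difference is flagged *meaningful* only when p < alpha
    and the absolute difference exceeds ``meaningful_pp`` points.
    """
    dq, rc = match_indicator_frames(dqq, recall)
    if dq.index.get_level_values("respondent_id").nunique() < 2:
        raise ValueError("prevalence comparison needs at least 2 respondents")
    x = dq[group.value].to_numpy().astype(float)
    y = rc[group.value].to_numpy().astype(float)
    p_dqq = 100.0 * x.mean()
    p_r24h = 100.0 * y.mean()
    diff = p_dqq - p_r24h
    resp = dq.index.get_level_values("respondent_id").to_numpy()
    stacked = np.concatenate([x, y])
    method = np.concatenate([np.ones_like(x), np.zeros_like(y)])
    p_value = _method_effect_pvalue(stacked, method, np.concatenate([resp, resp]))
    return PrevalenceComparison(
        group=group,
        p_dqq=p_dqq,
        p_r24h=p_r24h,
        diff_pp=diff,
        p_value=p_value,
        meaningful=is_meaningful(p_value, diff, alpha, meaningful_pp),
    )
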