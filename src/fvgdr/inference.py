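"""Score-level inference.

Four pieces, mirroring how dual-method dietary validation studies analyse
total scores:

* a paired Wilcoxon signed-rank test on the per-observation score
  difference between the two methods;
* standardized slopes (beta_st) from random-intercept linear mixed models
  of gram intake on each method's score — a correlation-like effect size
  that respects the two-days-per-respondent clustering;
* a comparison of two dependent, overlapping product-moment correlations
  (intake with each score) via Zou's confidence interval for r12 - r13 and
  the Hittner et al. modification of Dunn & Clark's z;
* an optimal score cut-off (Youden J) for classifying WHO-level intake
  (>= 400 g/day by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MixedModelFit",
    "WilcoxonResult",
    "CorrelationTriple",
    "DependentCorrelationComparison",
    "CutoffResult",
    "wilcoxon_paired",
    "mixed_beta_st",
    "compare_dependent_correlations",
    "cutoff_analysis",
]


@dataclass(frozen=True)
class MixedModelFit:
    """Standardized slope from a random-intercept linear mixed model."""

    beta_st: float
    ci_low: float
    ci_high: float
    sigma_u: float       # respondent random-intercept SD
    sigma_e: float       # residual SD
    n_obs: int
    n_respondents: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta_st <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    median_diff: float


@dataclass(frozen=True)
class CorrelationTriple:
    """Correlations for the overlapping dependent-correlation comparison.

    r12: intake vs. score-from-recall; r13: intake vs. score-from-
    questionnaire; r23: between the two scores; all plain product-moment
    correlations over n observations.
    """

    r12: float
    r13: float
    r23: float
    n: int

    def __post_init__(self) -> None:
        for name in ("r12", "r13", "r23"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {r}")

    @classmethod
    def from_data(
        cls,
        intake: Sequence[float],
        score_r24h: Sequence[float],
        score_dqq: Sequence[float],
    ) -> "CorrelationTriple":
        x = np.asarray(intake, dtype=float)
        y = np.asarray(score_r24h, dtype=float)
        z = np.asarray(score_dqq, dtype=float)
        if not (len(x) == len(y) == len(z)):
            raise ValueError("intake and score streams must have equal length")
        r = np.corrcoef(np.vstack([x, y, z]))
        return cls(r12=float(r[0, 1]), r13=float(r[0, 2]), r23=float(r[1, 2]), n=len(x))


@dataclass(frozen=True)
class DependentCorrelationComparison:
    z: float
    p_value: float
    zou_low: float   # bounds for r12 - r13
    zou_high: float


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float           # half-integer score threshold maximizing Youden J
    criterion_value: float  # Youden J at the optimum
    prop_dqq_above: float   # % of observations at/above the integer cut-off
    prop_r24h_above: float


def wilcoxon_paired(
    scores_dqq: Sequence[float], scores_r24h: Sequence[float]
) -> WilcoxonResult:
    """Paired signed-rank test on per-observation score differences.

    Zero differences are discarded (Wilcoxon's procedure); the normal
    approximation with tie correction is used beyond n = 25 non-zero
    pairs.  All-zero differences give statistic 0, p = 1.
    """
    x = np.asarray(scores_dqq, dtype=float)
    y = np.asarray(scores_r24h, dtype=float)
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("need equal-length, non-empty paired score streams")
    d = x - y
    nz = d[d != 0]
    median_diff = float(np.median(d))
    if len(nz) == 0:
        return WilcoxonResult(0.0, 1.0, median_diff)
    method = "approx" if len(nz) > 25 else "auto"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=False, method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), median_diff)


def mixed_beta_st(
    x: Sequence[float],
    y: Sequence[float],
    respondent_ids: Sequence,
) -> MixedModelFit:
    """Standardized slope of y on x with a respondent random intercept.

    Both variables are z-standardized over all observations, then
    y* = beta * x* + u_respondent + eps is fitted by REML; the 95% CI is
    the Wald interval on beta.  With one observation per respondent the
    estimate coincides with the ordinary standardized least-squares slope.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = np.asarray(respondent_ids)
    if not (len(x) == len(y) == len(ids)):
        raise ValueError("x, y and respondent_ids must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if len(np.unique(ids)) < 2:
        raise ValueError("need at least 2 respondents")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    xs = (x - x.mean()) / sx
    ys = (y - y.mean()) / sy

    n_resp = int(len(np.unique(ids)))
    exog = np.column_stack([np.ones_like(xs), xs])
    # Degenerate perfect fit: the mixed model has no residual variance to
    # estimate; the slope is +-1 with a collapsed interval.
    resid = ys - xs * float(np.dot(xs, ys) / np.dot(xs, xs))
    if float(np.dot(resid, resid)) / len(x) < 1e-12:
        b = float(np.sign(np.dot(xs, ys)))
        return MixedModelFit(b, b, b, 0.0, 0.0, len(x), n_resp)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(ys, exog, groups=ids)
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError:
            res = model.fit(reml=True, method="powell")
        if not res.converged:
            res = model.fit(reml=True, method="powell")
    if not res.converged:
        raise RuntimeError(
            "mixed model did not converge "
            f"(n_obs={len(x)}, n_respondents={n_resp}); "
            "check for degenerate inputs"
        )
    beta = float(res.fe_params[1])
    se = float(res.bse_fe[1])
    zc = stats.norm.ppf(0.975)
    sigma_u = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
    sigma_e = float(np.sqrt(max(res.scale, 0.0)))
    return MixedModelFit(
        beta_st=beta,
        ci_low=beta - zc * se,
        ci_high=beta + zc * se,
        sigma_u=sigma_u,
        sigma_e=sigma_e,
        n_obs=len(x),
        n_respondents=n_resp,
    )


def compare_dependent_correlations(
    t: CorrelationTriple, alpha: float = 0.05
) -> DependentCorrelationComparison:
    """Compare two dependent, overlapping correlations (r12 vs. r13).

    Hittner's z: Dunn & Clark's statistic on the Fisher transforms of r12
    and r13, with both correlations replaced in the covariance term by the
    back-transformed mean of their Fisher transforms.  Zou's interval for
    r12 - r13 combines the individual Fisher-interval limits with the
    estimated correlation between the two sample correlations.
    """
    r12, r13, r23, n = t.r12, t.r13, t.r23, t.n
    if n < 10:
        raise ValueError(f"need n >= 10 observations, got {n}")
    if abs(r12) >= 1.0 or abs(r13) >= 1.0:
        raise ValueError("compared correlations must satisfy |r| < 1")

    z12 = math.atanh(r12)
    z13 = math.atanh(r13)

    # Hittner z
    if z12 == z13:
        z = 0.0
    else:
        rbar = math.tanh((z12 + z13) / 2.0)
        cov = (
            r23 * (1.0 - 2.0 * rbar**2)
            - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r23**2)
        ) / (1.0 - rbar**2) ** 2
        denom = max(2.0 - 2.0 * cov, 1e-12)
        z = (z12 - z13) * math.sqrt((n - 3) / denom)
    p = 2.0 * stats.norm.sf(abs(z))

    # Zou interval for r12 - r13
    zc = stats.norm.ppf(1.0 - alpha / 2.0)
    half = zc / math.sqrt(n - 3)
    l1, u1 = math.tanh(z12 - half), math.tanh(z12 + half)
    l2, u2 = math.tanh(z13 - half), math.tanh(z13 + half)
    corr_rr = (
        (r23 - 0.5 * r12 * r13) * (1.0 - r12**2 - r13**2 - r23**2) + r23**3
    ) / ((1.0 - r12**2) * (1.0 - r13**2))
    diff = r12 - r13
    low = diff - math.sqrt(
        (r12 - l1) ** 2 + (u2 - r13) ** 2 - 2.0 * corr_rr * (r12 - l1) * (u2 - r13)
    )
    high = diff + math.sqrt(
        (u1 - r12) ** 2 + (r13 - l2) ** 2 - 2.0 * corr_rr * (u1 - r12) * (r13 - l2)
    )
    return DependentCorrelationComparison(z=z, p_value=float(p), zou_low=low, zou_high=high)


def cutoff_analysis(
    scores: Sequence[float],
    intake_g: Sequence[float],
    threshold_g: float = 400.0,
    *,
    report_cutoff: int = 3,
    scores_dqq: Optional[Sequence[float]] = None,
    scores_r24h: Optional[Sequence[float]] = None,
) -> CutoffResult:
    """Optimal score cut-off for classifying WHO-level F&V intake.

    Observations are labelled by intake >= ``threshold_g``; half-integer
    cut-offs -0.5, 0.5, ..., 6.5 of the score are swept and the one
    maximizing Youden J (sensitivity + specificity - 1) is returned (ties
    resolve to the smallest cut-off).  ``report_cutoff`` additionally
    yields the percentage of observations at/above an integer cut-off per
    method (defaulting both methods to ``scores`` when not supplied).
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(intake_g, dtype=float)
    if len(s) != len(g) or len(s) == 0:
        raise ValueError("scores and intake_g must be non-empty and matched")
    labels = g >= threshold_g
    if labels.all() or (~labels).all():
        raise ValueError(
            f"need observations on both sides of {threshold_g} g to fit a cut-off"
        )
    grid = np.arange(-0.5, 7.0, 1.0)
    best_j, best_cut = -np.inf, grid[0]
    for cut in grid:
        pred = s >= cut
        sens = float(np.mean(pred[labels]))
        spec = float(np.mean(~pred[~labels]))
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_cut = j, float(cut)
    sd = np.asarray(scores_dqq, dtype=float) if scores_dqq is not None else s
    sr = np.asarray(scores_r24h, dtype=float) if scores_r24h is not None else s
    return CutoffResult(
        cutoff=best_cut,
        criterion_value=best_j,
        prop_dqq_above=100.0 * float(np.mean(sd >= report_cutoff)),
        prop_r24h_above=100.0 * float(np.mean(sr >= report_cutoff)),
    )
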