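"""Score-level inference: Wilcoxon, mixed-model slopes, dependent
correlations, cut-off search — each checked against an independent oracle."""

import subprocess

import numpy as np
import pytest
from scipy import stats

from fvgdr.inference import (
    CorrelationTriple,
    compare_dependent_correlations,
    cutoff_analysis,
    mixed_beta_st,
    wilcoxon_paired,
)

# ---------------------------------------------------------------------------
# Wilcoxon paired test
# ---------------------------------------------------------------------------


def test_wilcoxon_identical_streams():
    s = [2, 3, 1, 4, 0, 5] * 5
    res = wilcoxon_paired(s, s)
    assert res.statistic == 0.0 and res.p_value == 1.0 and res.median_diff == 0.0


def test_wilcoxon_unit_shift():
    r24h = np.tile([0, 1, 2, 3, 4], 10)
    res = wilcoxon_paired(r24h + 1, r24h)
    assert res.p_value < 0.05
    assert res.median_diff == 1.0


def test_wilcoxon_against_signflip_permutation_oracle():
    """Normal-approximation p agrees with a 10,000-resample sign-flip null."""
    rng = np.random.default_rng(17)
    x = rng.integers(0, 7, 200).astype(float)
    y = np.clip(x + rng.integers(-2, 3, 200), 0, 6).astype(float)
    res = wilcoxon_paired(x, y)

    d = x - y
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    mu = ranks.sum() / 2.0
    t_obs = ranks[d > 0].sum()
    signs = rng.random((10_000, len(d))) < 0.5
    t_perm = (signs * ranks).sum(axis=1)
    p_perm = np.mean(np.abs(t_perm - mu) >= np.abs(t_obs - mu) - 1e-9)
    assert res.p_value == pytest.approx(p_perm, abs=0.02)


def test_wilcoxon_pvalues_uniform_under_null():
    """Continuous paired-null p-values pass a Kolmogorov-Smirnov check."""
    rng = np.random.default_rng(23)
    pvals = [
        wilcoxon_paired(rng.normal(size=40), rng.normal(size=40)).p_value
        for _ in range(400)
    ]
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# Random-intercept standardized slope
# ---------------------------------------------------------------------------


def test_beta_st_equals_ols_with_singleton_groups():
    rng = np.random.default_rng(3)
    n = 80
    x = rng.normal(size=n)
    y = 0.4 * x + rng.normal(size=n)
    fit = mixed_beta_st(x, y, np.arange(n))
    xs = (x - x.mean()) / x.std(ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    ols = float(np.dot(xs, ys) / np.dot(xs, xs))
    assert fit.beta_st == pytest.approx(ols, abs=1e-6)
    assert fit.ci_low <= fit.beta_st <= fit.ci_high


def test_beta_st_perfect_fit_collapses():
    x = np.arange(20.0)
    fit = mixed_beta_st(x, x, np.repeat(np.arange(10), 2))
    assert fit.beta_st == 1.0 and fit.ci_low == fit.ci_high == 1.0
    assert fit.sigma_u == fit.sigma_e == 0.0


def test_beta_st_input_validation():
    with pytest.raises(ValueError, match="variance"):
        mixed_beta_st([1, 1, 1, 1], [1, 2, 3, 4], [0, 0, 1, 1])
    with pytest.raises(ValueError, match="respondents"):
        mixed_beta_st([1, 2, 3], [1, 2, 3], [0, 0, 0])
    with pytest.raises(ValueError, match="finite"):
        mixed_beta_st([1, 2, np.nan, 4], [1, 2, 3, 4], [0, 0, 1, 1])


def test_beta_st_matches_lme4_reference():
    """Cross-check the REML fit against R's lmer on the same standardized data."""
    rng = np.random.default_rng(11)
    n_resp = 40
    ids = np.repeat([f"r{i}" for i in range(n_resp)], 2)
    grp = np.repeat(np.arange(n_resp), 2)
    x = rng.normal(size=2 * n_resp)
    y = 0.5 * x + rng.normal(0, 0.6, n_resp)[grp] + rng.normal(0, 0.8, 2 * n_resp)
    fit = mixed_beta_st(x, y, ids)

    xs = (x - x.mean()) / x.std(ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    lines = ["id,x,y"] + [
        f"{i},{float(a)!r},{float(b)!r}" for i, a, b in zip(ids, xs, ys)
    ]
    script = (
        "suppressMessages(library(lme4));"
        'd <- read.csv("stdin");'
        "m <- lmer(y ~ x + (1|id), data=d, REML=TRUE);"
        'cat(fixef(m)[["x"]], as.data.frame(VarCorr(m))$sdcor)'
    )
    proc = subprocess.run(
        ["Rscript", "-e", script],
        input="\n".join(lines),
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        pytest.fail(f"Rscript failed: {proc.stderr[-500:]}")
    beta_r, sigma_u_r, sigma_e_r = map(float, proc.stdout.split())
    assert fit.beta_st == pytest.approx(beta_r, abs=1e-4)
    assert fit.sigma_u == pytest.approx(sigma_u_r, abs=1e-3)
    assert fit.sigma_e == pytest.approx(sigma_e_r, abs=1e-3)


def test_beta_st_bounded_on_standardized_data():
    """|beta_st| stays <= 1 (+ numerical tolerance) across generated datasets."""
    for seed, slope, su in [(0, 0.2, 0.5), (1, 0.8, 0.3), (2, 0.0, 1.0), (3, 0.95, 0.1)]:
        rng = np.random.default_rng(seed)
        n_resp = 150
        grp = np.repeat(np.arange(n_resp), 2)
        x = rng.normal(size=2 * n_resp)
        e_sd = max(1 - slope**2 - su**2, 0.02) ** 0.5
        y = slope * x + rng.normal(0, su, n_resp)[grp] + rng.normal(0, e_sd, 2 * n_resp)
        fit = mixed_beta_st(x, y, grp)
        assert abs(fit.beta_st) <= 1.0 + 1e-6


# ---------------------------------------------------------------------------
# Dependent overlapping correlations
# ---------------------------------------------------------------------------


def test_equal_correlations_give_null_result():
    res = compare_dependent_correlations(CorrelationTriple(0.5, 0.5, 0.8, 100))
    assert res.z == 0.0 and res.p_value == 1.0
    assert res.zou_low == pytest.approx(-res.zou_high)
    assert res.zou_low < 0 < res.zou_high


@pytest.mark.parametrize(
    "r12, r13, r23, n",
    [(0.6, 0.4, 0.7, 500), (0.3, -0.2, 0.1, 50), (0.9, 0.85, 0.8, 200)],
)
def test_antisymmetry(r12, r13, r23, n):
    a = compare_dependent_correlations(CorrelationTriple(r12, r13, r23, n))
    b = compare_dependent_correlations(CorrelationTriple(r13, r12, r23, n))
    assert a.z == pytest.approx(-b.z)
    assert a.p_value == pytest.approx(b.p_value)
    assert a.zou_low == pytest.approx(-b.zou_high)
    assert a.zou_high == pytest.approx(-b.zou_low)


def test_zou_interval_brackets_difference():
    rng = np.random.default_rng(31)
    for _ in range(25):
        x = rng.standard_normal((60, 3)) @ rng.standard_normal((3, 3))
        r = np.corrcoef(x.T)
        t = CorrelationTriple(float(r[0, 1]), float(r[0, 2]), float(r[1, 2]), 60)
        res = compare_dependent_correlations(t)
        assert res.zou_low <= t.r12 - t.r13 <= res.zou_high


def test_degenerate_inputs_are_errors():
    with pytest.raises(ValueError, match="n >= 10"):
        compare_dependent_correlations(CorrelationTriple(0.5, 0.4, 0.3, 5))
    with pytest.raises(ValueError, match=r"\|r\| < 1"):
        compare_dependent_correlations(CorrelationTriple(1.0, 0.4, 0.3, 100))
    with pytest.raises(ValueError):
        CorrelationTriple(1.5, 0.0, 0.0, 100)


def test_power_matches_bootstrap_oracle():
    """Hittner-z rejections track a nonparametric bootstrap on the same data.

    Trivariate normal with population correlations (0.6, 0.4, 0.7); each
    replicate is tested two ways: the z test, and a 2,000-resample
    percentile bootstrap CI for r12 - r13 excluding 0.
    """
    rng = np.random.default_rng(41)
    C = np.array([[1.0, 0.6, 0.4], [0.6, 1.0, 0.7], [0.4, 0.7, 1.0]])
    L = np.linalg.cholesky(C)
    n, reps, nboot = 500, 120, 2000
    z_rej = np.zeros(reps, dtype=bool)
    b_rej = np.zeros(reps, dtype=bool)
    for i in range(reps):
        x = rng.standard_normal((n, 3)) @ L.T
        r = np.corrcoef(x.T)
        t = CorrelationTriple(float(r[0, 1]), float(r[0, 2]), float(r[1, 2]), n)
        z_rej[i] = compare_dependent_correlations(t).p_value < 0.05

        idx = rng.integers(0, n, (nboot, n))
        s = x[idx]  # (nboot, n, 3)
        m = s.mean(axis=1, keepdims=True)
        sc = s - m
        cov = np.einsum("bni,bnj->bij", sc, sc) / (n - 1)
        sd = np.sqrt(np.einsum("bii->bi", cov))
        d_boot = cov[:, 0, 1] / (sd[:, 0] * sd[:, 1]) - cov[:, 0, 2] / (sd[:, 0] * sd[:, 2])
        lo, hi = np.quantile(d_boot, [0.025, 0.975])
        b_rej[i] = not (lo <= 0.0 <= hi)
    diff = z_rej.astype(float) - b_rej.astype(float)
    se = max(diff.std(ddof=1) / np.sqrt(reps), 1.0 / reps)
    assert abs(diff.mean()) <= 3 * se


# ---------------------------------------------------------------------------
# Cut-off analysis
# ---------------------------------------------------------------------------


def test_cutoff_separable_case():
    scores = np.array([5, 6, 4, 5, 2, 1, 0, 2, 1, 0], dtype=float)
    intake = np.where(scores >= 4, 500.0, 200.0)
    res = cutoff_analysis(scores, intake)
    assert 2 < res.cutoff < 4
    assert res.criterion_value == pytest.approx(1.0)


def test_cutoff_uninformative_scores():
    rng = np.random.default_rng(2)
    scores = rng.integers(0, 7, 2000).astype(float)
    intake = rng.choice([200.0, 500.0], 2000)
    res = cutoff_analysis(scores, intake)
    assert abs(res.criterion_value) < 0.1


def test_cutoff_matches_exhaustive_enumeration():
    rng = np.random.default_rng(8)
    scores = rng.integers(0, 7, 500).astype(float)
    intake = rng.gamma(2.0, 150.0, 500) + 30 * scores
    res = cutoff_analysis(scores, intake, report_cutoff=3)
    labels = intake >= 400.0
    best = max(
        (
            (np.mean(scores[labels] >= c) + np.mean(scores[~labels] < c) - 1.0, -c)
            for c in np.arange(-0.5, 7.0, 1.0)
        ),
    )
    assert res.criterion_value == pytest.approx(best[0])
    assert res.prop_dqq_above == pytest.approx(100.0 * np.mean(scores >= 3))


def test_cutoff_single_class_error():
    with pytest.raises(ValueError, match="both sides"):
        cutoff_analysis([1.0, 2.0, 3.0], [500.0, 600.0, 700.0])
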