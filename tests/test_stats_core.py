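"""Unit and property tests for the shared statistical primitives.

Exact branches are checked against brute-force enumeration oracles
implemented here, independently of the library code path.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gradimmune import (
    adjust_pvalues,
    contingency_chi_square,
    fit_linear_model,
    kruskal_wallis,
    spearman_correlation,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# oracles

def enumerate_ranksum_p(x, y):
    """Exact two-sided rank-sum p by enumerating every label assignment."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    obs = sum(ranks[: n1])
    stats_all = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        stats_all.append(sum(ranks[list(idx)]))
    stats_all = np.asarray(stats_all)
    mu = stats_all.mean()
    return float(np.mean(np.abs(stats_all - mu) >= abs(obs - mu) - 1e-9))


def enumerate_spearman_p(x, y):
    """Exact permutation p for |rho| under shuffling of y."""
    rho_obs = abs(stats.spearmanr(x, y).statistic)
    count = total = 0
    for perm in itertools.permutations(y):
        r = abs(stats.spearmanr(x, perm).statistic)
        count += r >= rho_obs - 1e-12
        total += 1
    return count / total


def bh_stepup(p):
    """BH adjusted p-values by the step-up recursion, written directly."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return adj


# ---------------------------------------------------------------------------
# wilcoxon rank-sum

def test_ranksum_separated_triples():
    res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert res.p_value == pytest.approx(0.1)
    assert res.direction == -1
    assert "exact" in res.method_note


def test_ranksum_identical_samples_tie_branch():
    res = wilcoxon_rank_sum([5, 5, 5, 5], [5, 5, 5, 5])
    assert res.p_value == pytest.approx(1.0)
    assert res.direction == 0


def test_ranksum_single_observations():
    assert wilcoxon_rank_sum([1], [2]).p_value == pytest.approx(1.0)


def test_ranksum_empty_input_rejected():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1, 2])


@pytest.mark.parametrize("seed", range(8))
def test_ranksum_matches_enumeration_small_n(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(1, 6, 2)
    # distinct values keep the exact branch tie-free
    vals = rng.permutation(20)[: n1 + n2].astype(float)
    x, y = vals[:n1], vals[n1:]
    res = wilcoxon_rank_sum(x, y)
    assert res.p_value == pytest.approx(enumerate_ranksum_p(x, y), abs=1e-10)


def test_ranksum_one_sided_directions():
    lo, hi = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
    assert wilcoxon_rank_sum(lo, hi, "less").p_value < 0.1
    assert wilcoxon_rank_sum(lo, hi, "greater").p_value > 0.9


# ---------------------------------------------------------------------------
# spearman

def test_spearman_hand_example():
    res = spearman_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert res.statistic == pytest.approx(0.8)  # 1 - 6*4/(5*24)


def test_spearman_identity_and_reversal():
    x = [3.0, 1.0, 4.0, 1.5, 5.0]
    assert spearman_correlation(x, x).statistic == pytest.approx(1.0)
    assert spearman_correlation(x, [-v for v in x]).statistic == pytest.approx(-1.0)


def test_spearman_constant_input_flagged():
    res = spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
    assert np.isnan(res.statistic)
    assert "constant" in res.method_note


@pytest.mark.parametrize("seed", range(4))
def test_spearman_p_close_to_exact_permutation_small_n(seed):
    rng = np.random.default_rng(100 + seed)
    x = rng.normal(size=6)
    y = rng.normal(size=6)
    approx = spearman_correlation(x, y).p_value
    exact = enumerate_spearman_p(x, y)
    # the t-approximation is close but not identical at tiny n
    assert approx == pytest.approx(exact, abs=0.08)


# integer grid keeps every transform strictly monotone in float arithmetic
@given(st.lists(st.integers(-10_000, 10_000), min_size=4, max_size=12, unique=True),
       st.sampled_from([np.exp, np.cbrt, lambda v: 3 * v + 7]))
@settings(max_examples=40, deadline=None)
def test_spearman_invariant_under_monotone_transform(xs, f):
    xs = np.asarray(xs, float) / 1000.0
    rng = np.random.default_rng(7)
    ys = rng.normal(size=len(xs))
    base = spearman_correlation(xs, ys).statistic
    trans = spearman_correlation(f(xs), ys).statistic
    assert trans == pytest.approx(base, abs=1e-10)


# ---------------------------------------------------------------------------
# multiple testing

def test_bh_hand_example():
    out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
    assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_single_pvalue_unchanged():
    assert adjust_pvalues([0.5], "BH") == pytest.approx([0.5])
    assert adjust_pvalues([0.5], "bonferroni") == pytest.approx([0.5])


def test_bonferroni_multiplies_and_clips():
    assert adjust_pvalues([0.3, 0.0004], "bonferroni") == pytest.approx([0.6, 0.0008])
    assert adjust_pvalues([0.9, 0.8], "bonferroni") == pytest.approx([1.0, 1.0])


def test_invalid_pvalues_rejected():
    with pytest.raises(ValueError):
        adjust_pvalues([0.5, 1.5], "BH")


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(max_examples=60, deadline=None)
def test_bh_matches_stepup_recursion_and_order_invariance(ps):
    out = adjust_pvalues(ps, "BH")
    assert out == pytest.approx(bh_stepup(ps), abs=1e-12)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(ps))
    shuffled = adjust_pvalues(np.asarray(ps)[perm], "BH")
    assert shuffled == pytest.approx(out[perm], abs=1e-12)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(max_examples=30, deadline=None)
def test_bonferroni_dominates_raw(ps):
    out = adjust_pvalues(ps, "bonferroni")
    assert np.all(out >= np.asarray(ps) - 1e-15)
    assert np.all(out <= 1.0)


# ---------------------------------------------------------------------------
# chi-square & kruskal-wallis

def test_chi_square_residency_example():
    res = contingency_chi_square([[11, 11], [59, 242]])
    assert round(res.p_value, 3) == 0.002
    assert "Yates" in res.method_note


def test_chi_square_perfect_independence():
    res = contingency_chi_square([[5, 5], [5, 5]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_diagonal_without_correction():
    res = contingency_chi_square([[10, 0], [0, 10]], continuity_correction=False)
    assert res.statistic == pytest.approx(20.0)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError):
        contingency_chi_square([[0, 0], [3, 4]])


def test_kruskal_hand_ranks():
    groups = [[1, 2], [3, 4], [5, 6]]
    # H = 12/(N(N+1)) * sum n_g rbar_g^2 - 3(N+1), ranks 1..6
    h_hand = 12 / (6 * 7) * (2 * 1.5**2 + 2 * 3.5**2 + 2 * 5.5**2) - 3 * 7
    res = kruskal_wallis(groups)
    assert res.statistic == pytest.approx(h_hand)
    assert res.p_value == pytest.approx(stats.chi2.sf(h_hand, 2))


def test_kruskal_degenerate_identical_groups():
    res = kruskal_wallis([[2, 2, 2], [2, 2, 2]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kruskal_empty_group_rejected():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2], []])


# ---------------------------------------------------------------------------
# linear model

def test_ols_noiseless_exact_recovery():
    x = np.linspace(0, 1, 30)
    X = np.column_stack([np.ones(30), x])
    y = 2.0 + 3.0 * x
    fit = fit_linear_model(X, y, ["intercept", "x"])
    assert fit.coefficients["x"] == pytest.approx(3.0, abs=1e-12)
    assert fit.coefficients["intercept"] == pytest.approx(2.0, abs=1e-12)


def test_ols_closed_form_simple_slope(rng):
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    X = np.column_stack([np.ones(50), x])
    fit = fit_linear_model(X, y, ["intercept", "x"])
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    assert fit.coefficients["x"] == pytest.approx(slope, abs=1e-12)


def test_ols_matches_statsmodels(rng):
    import statsmodels.api as sm

    X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
    y = rng.normal(size=40)
    fit = fit_linear_model(X, y, ["c", "a", "b"])
    ref = sm.OLS(y, X).fit()
    assert fit.coefficients["b"] == pytest.approx(ref.params[2], abs=1e-10)
    assert fit.std_errors["b"] == pytest.approx(ref.bse[2], abs=1e-10)
    assert fit.p_values["b"] == pytest.approx(ref.pvalues[2], abs=1e-10)


def test_ols_duplicated_column_flags_rank_deficiency(rng):
    x = rng.normal(size=20)
    X = np.column_stack([np.ones(20), x, x])
    fit = fit_linear_model(X, rng.normal(size=20), ["c", "x1", "x2"])
    assert fit.rank_deficient
    assert "x2" in fit.aliased
    assert np.isnan(fit.coefficients["x2"])
    assert np.isfinite(fit.coefficients["x1"])


def test_ols_zero_residual_df_returns_coefficients():
    X = np.array([[1.0, 0.0], [0.0, 1.0]])
    fit = fit_linear_model(X, [1.0, 2.0], ["a", "b"])
    assert fit.coefficients["a"] == pytest.approx(1.0)
    assert np.isnan(fit.p_values["a"])


def test_ols_ci_coverage_monte_carlo():
    """95% CIs for (2, 3) cover the truth in >=90% of 100 replicates."""
    from scipy.stats import t as t_dist

    cover = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=200)
        y = 2.0 + 3.0 * x + rng.normal(size=200)
        fit = fit_linear_model(np.column_stack([np.ones(200), x]), y, ["b0", "b1"])
        tcrit = t_dist.ppf(0.975, fit.df_resid)
        ok = all(
            abs(fit.coefficients[n] - truth) <= tcrit * fit.std_errors[n]
            for n, truth in (("b0", 2.0), ("b1", 3.0))
        )
        cover += ok
    assert cover >= 90
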