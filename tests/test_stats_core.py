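"""Statistical primitives against brute-force oracles and scipy/statsmodels."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from phosvar import stats_core as S


# ---------------------------------------------------------------------------
# oracles


def ks_d_bruteforce(x, y):
    """Max ECDF distance evaluated at every pooled breakpoint."""
    pts = sorted(set(x) | set(y))
    best = 0.0
    for t in pts:
        fx = sum(v <= t for v in x) / len(x)
        fy = sum(v <= t for v in y) / len(y)
        best = max(best, abs(fx - fy))
    return best


def mww_u_bruteforce(x, y):
    """Count pairs x > y, ties 1/2."""
    return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y)


def fisher_p_enumeration(a, b, c, d):
    """Two-sided p by exhaustive enumeration of tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(r1 + r2, c1)
        )
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7))


def anova_f_ss(groups):
    """F from the explicit sum-of-squares decomposition."""
    allv = [v for g in groups for v in g]
    grand = sum(allv) / len(allv)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


@pytest.mark.parametrize(
    "x, y, expected_d",
    [
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
        ([1, 2, 3], [4, 5, 6], 1.0),  # disjoint ranges: ECDFs never overlap
        ([1, 3], [2, 4], 0.5),  # frozen from the brute-force ECDF scan
    ],
)
def test_ks_statistic_examples(x, y, expected_d):
    assert S.ks_two_sample(x, y).statistic == pytest.approx(expected_d)


def kolmogorov_series(t, terms=200):
    """Survival function of the Kolmogorov distribution by its series."""
    if t <= 0:
        return 1.0
    return min(1.0, 2.0 * sum(
        (-1) ** (k - 1) * math.exp(-2.0 * k * k * t * t) for k in range(1, terms + 1)
    ))


def test_ks_matches_bruteforce_oracle(rng):
    for _ in range(50):
        x = rng.standard_normal(rng.integers(2, 30))
        y = rng.standard_normal(rng.integers(2, 30))
        res = S.ks_two_sample(x, y)
        assert res.statistic == pytest.approx(ks_d_bruteforce(list(x), list(y)), abs=1e-12)
        assert res.statistic == pytest.approx(
            scipy.stats.ks_2samp(x, y).statistic, abs=1e-12
        )
        en = math.sqrt(x.size * y.size / (x.size + y.size))
        assert res.pvalue == pytest.approx(kolmogorov_series(en * res.statistic), abs=1e-9)


def test_ks_pvalue_agrees_with_scipy_at_large_n(rng):
    # the limiting-distribution p and scipy's finite-n asymptotic agree
    # closely once both samples are large
    x = rng.standard_normal(2000)
    y = rng.standard_normal(2000) + 0.05
    res = S.ks_two_sample(x, y)
    ref = scipy.stats.ks_2samp(x, y, method="asymp")
    assert res.pvalue == pytest.approx(ref.pvalue, rel=0.1, abs=0.005)


_grid_floats = st.integers(-5_000_000, 5_000_000).map(lambda i: i / 1e5)


@settings(deadline=None, max_examples=40)
@given(
    x=st.lists(_grid_floats, min_size=2, max_size=20),
    y=st.lists(_grid_floats, min_size=2, max_size=20),
)
def test_ks_invariant_under_monotone_transform(x, y):
    d0 = S.ks_two_sample(x, y).statistic
    f = lambda v: math.exp(0.1 * v) + 3 * v  # strictly increasing
    d1 = S.ks_two_sample([f(v) for v in x], [f(v) for v in y]).statistic
    assert d0 == pytest.approx(d1, abs=1e-12)


def test_ks_empty_rejected():
    with pytest.raises(ValueError):
        S.ks_two_sample([], [1.0])


# ---------------------------------------------------------------------------
# ANOVA


def test_anova_equal_means_gives_zero_f():
    res = S.anova_oneway([[1, 2, 3], [3, 2, 1]])
    assert res.statistic == pytest.approx(0.0)
    assert res.pvalue == pytest.approx(1.0)


def test_anova_zero_within_variance_is_flagged():
    res = S.anova_oneway([[0, 0], [1, 1]])
    assert res.degenerate
    assert res.statistic == math.inf
    assert res.pvalue == 0.0


def test_anova_matches_ss_oracle_and_scipy(rng):
    groups = [[1, 2], [2, 3], [3, 4]]
    res = S.anova_oneway(groups)
    assert res.statistic == pytest.approx(anova_f_ss(groups))
    for _ in range(20):
        gs = [list(rng.normal(rng.normal(), 1, size=rng.integers(3, 12))) for _ in range(3)]
        res = S.anova_oneway(gs)
        ref = scipy.stats.f_oneway(*gs)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-7, abs=1e-12)


def test_anova_rejects_degenerate_input():
    with pytest.raises(ValueError):
        S.anova_oneway([[1, 2, 3]])
    with pytest.raises(ValueError):
        S.anova_oneway([[1], [2, 3]])
    with pytest.raises(ValueError):
        S.anova_oneway([[2, 2], [2, 2]])


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mww_symmetry_and_convention():
    x = [1.0, 2.0, 3.0]
    assert S.mann_whitney(x, x).statistic == pytest.approx(len(x) ** 2 / 2)
    # all of x below all of y: U (pairs x > y) is zero
    assert S.mann_whitney([1, 2], [3, 4]).statistic == pytest.approx(0.0)


def test_mww_matches_pair_counting_and_scipy(rng):
    assert S.mann_whitney([1, 3, 5], [2, 4]).statistic == pytest.approx(
        mww_u_bruteforce([1, 3, 5], [2, 4])
    )
    for _ in range(30):
        x = rng.integers(0, 8, size=rng.integers(3, 15)).astype(float)
        y = rng.integers(0, 8, size=rng.integers(3, 15)).astype(float)
        res = S.mann_whitney(x, y)
        assert res.statistic == pytest.approx(mww_u_bruteforce(list(x), list(y)))
        if res.statistic != len(x) * len(y) / 2:  # scipy errors when var==0
            ref = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# Fisher


def test_fisher_perfect_independence():
    res = S.fisher_exact(S.ContingencyTable2x2(10, 10, 10, 10))
    assert res.odds_ratio == pytest.approx(1.0, abs=1e-9)
    assert res.pvalue == pytest.approx(1.0)


def test_fisher_empty_cell_bounds():
    assert S.fisher_exact(S.ContingencyTable2x2(0, 10, 10, 10)).odds_ratio == 0.0
    assert S.fisher_exact(S.ContingencyTable2x2(10, 0, 10, 10)).odds_ratio == math.inf


def test_fisher_derived_example_matches_enumeration():
    a, b, c, d = 12, 5, 7, 15
    res = S.fisher_exact(S.ContingencyTable2x2(a, b, c, d))
    assert res.pvalue == pytest.approx(fisher_p_enumeration(a, b, c, d), abs=1e-12)
    ref = scipy.stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
    assert res.odds_ratio == pytest.approx(ref.statistic, abs=1e-6)


def test_fisher_zero_margin_rejected():
    with pytest.raises(ValueError):
        S.fisher_exact(S.ContingencyTable2x2(0, 0, 5, 5))


def test_fisher_sweep_small_margins():
    """Exhaustive check against the enumeration oracle and scipy for all
    tables with every margin <= 6."""
    checked = 0
    for a, b, c, d in itertools.product(range(7), repeat=4):
        if a + b > 6 or c + d > 6 or a + c > 6 or b + d > 6:
            continue
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        t = S.ContingencyTable2x2(a, b, c, d)
        res = S.fisher_exact(t)
        assert res.pvalue == pytest.approx(fisher_p_enumeration(a, b, c, d), abs=1e-9)
        ref = scipy.stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
        if math.isinf(res.odds_ratio):
            assert math.isinf(ref.statistic)
        else:
            assert res.odds_ratio == pytest.approx(ref.statistic, abs=1e-6)
        checked += 1
    assert checked > 400


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


@pytest.mark.parametrize(
    "p, q",
    [
        ([0.05], [0.05]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),  # step-up formula
    ],
)
def test_bh_examples(p, q):
    assert S.bh_fdr(p) == pytest.approx(q)


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(20):
        p = rng.random(rng.integers(1, 40))
        q = S.bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert q == pytest.approx(ref, abs=1e-12)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_properties(p):
    q = S.bh_fdr(p)
    assert np.all(q >= np.asarray(p) - 1e-15)
    assert np.all(q <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone after sorting


def test_bh_small_p_control():
    alpha, n = 0.05, 10
    p = [alpha / n * 0.99] * n
    assert np.all(S.bh_fdr(p) <= alpha)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        S.bh_fdr([0.5, 1.2])
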