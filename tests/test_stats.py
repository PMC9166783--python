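"""Statistical primitives: worked examples recomputed from published group
summaries, exact small-sample oracles, and invariance properties."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from immunobehav.stats import (SummaryStat, bh_adjust, chi_square_2x2,
                               hedges_g, kruskal_wallis, mann_whitney_u,
                               one_sample_t, pooled_cohens_d, spearman_fdr)


# ---------------------------------------------------------------- one-sample t
@pytest.mark.parametrize("mean, sd, n, t_expected, df_expected", [
    # published change-score rows of the three responder groups
    (2.15, 1.13, 17, 7.84, 16),     # best group, CARS social impairment
    (-14.50, 10.46, 18, -5.88, 17), # least group, IFN-gamma
    (3.32, 1.47, 17, 9.31, 16),    # best group, CARS total (recomputed)
])
def test_one_sample_t_worked_examples(mean, sd, n, t_expected, df_expected):
    res = one_sample_t(SummaryStat(mean, sd, n))
    assert res.statistic == pytest.approx(t_expected, abs=0.005)
    assert res.df == df_expected


def test_one_sample_t_zero_mean():
    res = one_sample_t(SummaryStat(0.0, 2.0, 12))
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_one_sample_t_degenerate_sd():
    with pytest.raises(ValueError):
        one_sample_t(SummaryStat(1.0, 0.0, 10))


def test_one_sample_t_matches_scipy_on_raw_data():
    rng = np.random.default_rng(0)
    x = rng.normal(0.4, 1.0, 23)
    res = one_sample_t(SummaryStat(x.mean(), x.std(ddof=1), x.size))
    ref = sps.ttest_1samp(x, 0.0)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)


# ------------------------------------------------------------------- Hedges g
@pytest.mark.parametrize("mean, sd, n, g_expected", [
    (1.03, 0.96, 18, 1.02),       # least group, CARS total
    (-698.83, 623.10, 18, -1.07), # least group, MIG
    (2.15, 1.13, 17, 1.81),       # best group, CARS social impairment
])
def test_hedges_g_worked_examples(mean, sd, n, g_expected):
    assert hedges_g(SummaryStat(mean, sd, n)) == pytest.approx(g_expected, abs=0.005)


def test_hedges_g_zero_mean_and_errors():
    assert hedges_g(SummaryStat(0.0, 3.0, 9)) == 0.0
    with pytest.raises(ValueError):
        hedges_g(SummaryStat(1.0, 0.0, 9))


def test_hedges_g_exact_correction_close_to_approximation():
    approx = hedges_g(SummaryStat(1.0, 1.0, 17))
    exact = hedges_g(SummaryStat(1.0, 1.0, 17), exact_correction=True)
    assert exact == pytest.approx(approx, abs=0.001)


@given(st.floats(0.1, 100), st.floats(-5, 5), st.floats(0.2, 8))
@settings(max_examples=50, deadline=None)
def test_t_and_g_scale_invariant(c, mean, sd):
    base = SummaryStat(mean, sd, 15)
    scaled = SummaryStat(mean * c, sd * c, 15)
    assert one_sample_t(base).statistic == pytest.approx(
        one_sample_t(scaled).statistic, rel=1e-9)
    assert hedges_g(base) == pytest.approx(hedges_g(scaled), rel=1e-9)


@pytest.mark.parametrize("n", [40, 100, 500])
def test_hedges_g_approaches_cohens_d(n):
    d = 1.3
    g = hedges_g(SummaryStat(1.3, 1.0, n))
    assert abs(g - d) < 0.02 * abs(d)


# Full published change table of the three responder groups:
# (variable, group, mean, sd, n, printed t, printed g). The printed mean/SD
# are rounded, so recomputed t and g can differ from print by up to ~0.08
# and ~0.03 respectively; tolerances reflect that printing precision.
PUBLISHED_CHANGE_TABLE = [
    ("CARS_total", "best", 3.32, 1.47, 17, 9.34, 2.16),
    ("CARS_total", "least", 1.03, 0.96, 18, 4.53, 1.02),
    ("CARS_total", "medium", 1.41, 0.97, 44, 9.61, 1.42),
    ("CARS_S", "best", 2.15, 1.13, 17, 7.84, 1.81),
    ("CARS_S", "least", 0.64, 0.87, 18, 3.11, 0.70),
    ("CARS_S", "medium", 0.86, 0.76, 44, 7.56, 1.14),
    ("CARS_N", "best", 0.35, 0.58, 17, 2.51, 0.58),
    ("CARS_N", "least", 0.69, 0.55, 18, 5.40, 1.21),
    ("CARS_N", "medium", 0.20, 0.52, 44, 2.61, 0.39),
    ("CARS_D", "best", 0.91, 0.51, 17, 7.41, 1.71),
    ("CARS_D", "least", -0.06, 0.42, 18, -0.57, -0.13),
    ("CARS_D", "medium", 0.39, 0.34, 44, 7.57, 1.14),
    ("IFN-g", "best", -0.37, 14.72, 17, -0.10, -0.02),
    ("IFN-g", "least", -14.50, 10.46, 18, -5.88, -1.32),
    ("IFN-g", "medium", -3.83, 9.54, 44, -2.66, -0.39),
    ("IFN-a2", "best", 11.15, 12.60, 17, 3.65, 0.84),
    ("IFN-a2", "least", -1.63, 7.87, 18, -0.88, -0.20),
    ("IFN-a2", "medium", 4.68, 10.00, 44, 3.10, 0.46),
    ("MIG", "best", 586.62, 777.11, 17, 3.11, 0.72),
    ("MIG", "least", -698.83, 623.10, 18, -4.76, -1.07),
    ("MIG", "medium", -6.53, 470.77, 44, -0.09, -0.01),
]


@pytest.mark.parametrize(
    "variable, group, mean, sd, n, t_ref, g_ref", PUBLISHED_CHANGE_TABLE,
    ids=[f"{v}-{g}" for v, g, *_ in PUBLISHED_CHANGE_TABLE])
def test_full_published_change_table_recomputes(variable, group, mean, sd, n,
                                                t_ref, g_ref):
    stat = SummaryStat(mean, sd, n)
    res = one_sample_t(stat)
    assert res.statistic == pytest.approx(t_ref, abs=0.09)
    assert res.df == n - 1
    assert hedges_g(stat) == pytest.approx(g_ref, abs=0.03)


# ------------------------------------------------------------ pooled Cohen's d
def test_pooled_cohens_d_published_value():
    # discovery and validation CARS-total improvements merge to d = 1.26
    d = pooled_cohens_d(SummaryStat(1.54, 1.40, 37), SummaryStat(1.90, 1.34, 42))
    assert d == pytest.approx(1.26, abs=0.005)


def test_pooled_cohens_d_matches_raw_merge():
    rng = np.random.default_rng(1)
    a, b = rng.normal(1.0, 1.0, 37), rng.normal(1.6, 1.3, 42)
    d = pooled_cohens_d(SummaryStat(a.mean(), a.std(ddof=1), a.size),
                        SummaryStat(b.mean(), b.std(ddof=1), b.size))
    merged = np.concatenate([a, b])
    assert d == pytest.approx(merged.mean() / merged.std(ddof=1), rel=1e-12)


def test_pooled_cohens_d_symmetric_cancellation():
    d = pooled_cohens_d(SummaryStat(0.7, 1.0, 20), SummaryStat(-0.7, 1.0, 20))
    assert d == pytest.approx(0.0, abs=1e-12)


def test_pooled_cohens_d_identical_groups_large_n():
    d = pooled_cohens_d(SummaryStat(2.0, 1.0, 5000), SummaryStat(2.0, 1.0, 5000))
    assert d == pytest.approx(2.0, rel=1e-3)


def test_pooled_cohens_d_degenerate_inputs():
    with pytest.raises(ValueError):
        pooled_cohens_d(SummaryStat(1, 0, 5), SummaryStat(1, 1, 5))
    with pytest.raises(ValueError):  # n >= 2 enforced at construction
        SummaryStat(1, 1, 1)


# --------------------------------------------------------------- Mann-Whitney
def test_mann_whitney_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    res = mann_whitney_u(x, list(x))
    assert res.p_value > 0.9


def test_mann_whitney_complete_separation():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert min(res.statistic, 9 - res.statistic) == 0.0


def test_mann_whitney_exact_matches_enumeration():
    x = [0.3, 1.7, 2.2]
    y = [0.9, 2.8, 4.1]
    res = mann_whitney_u(x, y)
    # brute force: U distribution over all C(6,3) assignments of the pooled
    # sample to the x-group
    pooled = np.array(x + y)
    ranks = sps.rankdata(pooled)
    n_x = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    u_obs = min(u_obs, len(x) * len(y) - u_obs)
    count = 0
    total = 0
    for comb in itertools.combinations(range(6), n_x):
        r = ranks[list(comb)].sum()
        u = r - n_x * (n_x + 1) / 2
        u = min(u, len(x) * len(y) - u)
        total += 1
        count += u <= u_obs
    assert res.p_value == pytest.approx(count / total, abs=1e-12)


def test_mann_whitney_empty_input():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ------------------------------------------------------------------ chi-square
def test_chi_square_balanced_table():
    res = chi_square_2x2([[10, 10], [10, 10]])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1


def test_chi_square_matches_textbook_formula():
    a, b, c, d = 7, 30, 10, 32
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    res = chi_square_2x2([[a, b], [c, d]])
    assert res.statistic == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("n", [10, 25])
def test_chi_square_diagonal_table_closed_form(n):
    res = chi_square_2x2([[0, n], [n, 0]])
    assert res.statistic == pytest.approx(2 * n)
    assert res.p_value < 0.001


def test_chi_square_zero_marginal():
    with pytest.raises(ValueError):
        chi_square_2x2([[0, 0], [5, 5]])


def test_chi_square_continuity_flag_reduces_statistic():
    plain = chi_square_2x2([[7, 30], [10, 32]])
    yates = chi_square_2x2([[7, 30], [10, 32]], continuity=True)
    assert yates.statistic < plain.statistic


# ----------------------------------------------------------------- Spearman/FDR
def test_spearman_monotone_transform_gives_rho_one():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(30, 3))
    y = np.exp(x[:, 1])  # monotone transform of column 1
    table = spearman_fdr(x, y)
    assert table.loc[1, "rho"] == pytest.approx(1.0)


def test_bh_hand_computation():
    q = bh_adjust([0.01, 0.02, 0.04])
    assert np.allclose(q, [0.03, 0.03, 0.04])


def test_bh_monotone_and_bounded():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=40)
    q = bh_adjust(p)
    assert (q <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_spearman_constant_column_excluded():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(20, 3))
    x[:, 0] = 5.0
    table = spearman_fdr(x, rng.normal(size=20))
    assert np.isnan(table.loc[0, "rho"]) and np.isnan(table.loc[0, "q"])
    assert table.loc[[1, 2], "q"].notna().all()


def test_spearman_fdr_type_one_control_under_null():
    rng = np.random.default_rng(5)
    hits = 0
    reps = 100
    for _ in range(reps):
        x = rng.normal(size=(50, 35))
        y = rng.normal(size=50)
        table = spearman_fdr(x, y)
        hits += int((table["q"] < 0.05).sum())
    assert hits / (reps * 35) < 0.01


# -------------------------------------------------------------- Kruskal-Wallis
def test_kruskal_identical_groups():
    g = [1.0, 2.0, 3.0]
    res = kruskal_wallis([g, list(g), list(g)])
    assert res.statistic == 0.0
    assert res.df == 2


def test_kruskal_df_three_groups():
    rng = np.random.default_rng(6)
    res = kruskal_wallis([rng.normal(size=8), rng.normal(size=9),
                          rng.normal(size=7)])
    assert res.df == 2


def test_kruskal_small_instance_against_enumeration():
    groups = [[1.2, 3.4], [0.5, 2.2], [4.1, 5.5, 2.9]]
    res = kruskal_wallis(groups)
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    def h_stat(values_by_group):
        ranks = sps.rankdata(np.concatenate(values_by_group))
        n = ranks.size
        out, start = 0.0, 0
        for size in sizes:
            r = ranks[start:start + size]
            out += r.sum() ** 2 / size
            start += size
        return 12.0 / (n * (n + 1)) * out - 3 * (n + 1)

    h_obs = h_stat(groups)
    assert res.statistic == pytest.approx(h_obs, rel=1e-9)
    count = total = 0
    for perm in itertools.permutations(range(7)):
        vals = pooled[list(perm)]
        split = [vals[:2], vals[2:4], vals[4:]]
        total += 1
        count += h_stat(split) >= h_obs - 1e-12
    p_exact = count / total
    # chi-square approximation vs exact permutation null at n = 7
    assert res.p_value == pytest.approx(p_exact, abs=0.08)


def test_kruskal_empty_group():
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0, 2.0], []])
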