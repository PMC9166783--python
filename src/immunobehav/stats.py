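"""Statistical primitives shared by every analysis stage.

Effect sizes for within-group change scores (one-sample t, Hedges g,
pooled Cohen's d), rank tests for between-set comparisons (Mann-Whitney U,
Kruskal-Wallis), a 2x2 chi-square for sex proportions, and Spearman
correlation screens with Benjamini-Hochberg FDR control.

All tests are two-sided. Summary-statistic entry points exist because the
group-level change tables of the source study report only (mean, SD, n);
the same numbers are exactly recomputable from those triples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SummaryStat",
    "TestResult",
    "one_sample_t",
    "hedges_g",
    "pooled_cohens_d",
    "mann_whitney_u",
    "chi_square_2x2",
    "spearman_fdr",
    "kruskal_wallis",
    "bh_adjust",
]


@dataclass(frozen=True)
class SummaryStat:
    """Mean, SD and sample size of one variable in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a univariate test."""

    statistic: float
    p_value: float
    df: Optional[float] = None
    effect_size: Optional[float] = None
    effect_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


def one_sample_t(stat: SummaryStat) -> TestResult:
    """One-sample t-test of mean = 0 from summary statistics.

    t = mean / (sd / sqrt(n)), df = n - 1, two-sided p.
    """
    if stat.sd == 0:
        raise ValueError("one_sample_t is degenerate for sd = 0")
    df = stat.n - 1
    t = stat.mean / (stat.sd / np.sqrt(stat.n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), p_value=max(float(p), np.finfo(float).tiny),
                      df=float(df), effect_size=hedges_g(stat), effect_name="hedges_g")


def hedges_g(stat: SummaryStat, exact_correction: bool = False) -> float:
    """Small-sample-corrected standardized mean change.

    g = (mean / sd) * J with J = 1 - 3 / (4*(n-1) - 1) by default; the
    exact gamma-function correction J = Gamma(df/2) / (sqrt(df/2) *
    Gamma((df-1)/2)) is available behind a flag.
    """
    if stat.sd == 0:
        raise ValueError("hedges_g undefined for sd = 0")
    df = stat.n - 1
    if exact_correction:
        j = float(np.exp(special.gammaln(df / 2.0)
                         - special.gammaln((df - 1) / 2.0)) / np.sqrt(df / 2.0))
    else:
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(stat.mean / stat.sd * j)


def pooled_cohens_d(stat_a: SummaryStat, stat_b: SummaryStat) -> float:
    """One-sample Cohen's d of two groups' change scores merged exactly.

    The merge reconstructs the mean and SD the pooled sample would have:
    combined sum of squares adds each group's within-SS and its shift from
    the combined mean; the combined SD uses divisor (n_a + n_b - 1).
    """
    if stat_a.sd <= 0 or stat_b.sd <= 0:
        raise ValueError("both groups need sd > 0")
    na, nb = stat_a.n, stat_b.n
    if na + nb < 3:
        raise ValueError("need at least 3 subjects in total")
    m = (na * stat_a.mean + nb * stat_b.mean) / (na + nb)
    ss = ((na - 1) * stat_a.sd**2 + (nb - 1) * stat_b.sd**2
          + na * (stat_a.mean - m) ** 2 + nb * (stat_b.mean - m) ** 2)
    sd = np.sqrt(ss / (na + nb - 1))
    return float(m / sd)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration when n_x * n_y <= 200 and there are no ties,
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size * y.size <= 200 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic),
                      p_value=min(1.0, float(res.pvalue)))


def chi_square_2x2(table, continuity: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 count table (df = 1).

    Yates continuity correction is off by default.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() <= 0:
        raise ValueError("table total must be positive")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column marginal")
    stat, p, df, _ = sps.chi2_contingency(t, correction=continuity)
    return TestResult(statistic=float(stat), p_value=min(1.0, max(float(p), np.finfo(float).tiny)),
                      df=float(df))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def spearman_fdr(x_matrix, y) -> "pd.DataFrame":
    """Per-column Spearman correlation of x_matrix against y, with BH FDR.

    Constant columns have undefined rho; they are reported as NaN and
    excluded from the FDR family.
    """
    import pandas as pd

    y = np.asarray(y, dtype=float)
    if isinstance(x_matrix, pd.DataFrame):
        names = list(x_matrix.columns)
        x = x_matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(x_matrix, dtype=float)
        names = [f"x{j}" for j in range(x.shape[1])]
    if x.shape[0] != y.size:
        raise ValueError("x_matrix and y must have the same number of rows")
    if y.size < 4:
        raise ValueError("need n >= 4")

    rho = np.full(x.shape[1], np.nan)
    p = np.full(x.shape[1], np.nan)
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.unique(col).size < 2 or np.unique(y).size < 2:
            continue
        r_j, p_j = sps.spearmanr(col, y)
        rho[j], p[j] = r_j, p_j
    q = np.full(x.shape[1], np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    return pd.DataFrame({"variable": names, "rho": rho, "p": p, "q": q})


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H across >= 2 groups, tie-corrected, chi-square p."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        # All observations identical: H = 0 by definition; scipy raises.
        return TestResult(statistic=0.0, p_value=1.0, df=float(df))
    stat, p = sps.kruskal(*arrays)
    return TestResult(statistic=float(stat), p_value=min(1.0, max(float(p), np.finfo(float).tiny)),
                      df=float(df))
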