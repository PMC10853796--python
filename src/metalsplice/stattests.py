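"""Statistical tests used throughout the exon comparisons.

Thin, uniformly-typed wrappers over scipy.stats: one-way ANOVA with a
Tukey-Kramer post-hoc table, Kruskal-Wallis, Mann-Whitney U, the 2x2
median test, Pearson chi-square on contingency tables, and the exact
binomial test.  Results come back as :class:`TestResult` records so the
pipeline can serialize them with method metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    sidedness: str = "two"
    df: float | tuple[float, float] | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if not np.isfinite(self.statistic):
            raise ValueError("non-finite test statistic")

    def to_dict(self) -> dict:
        return asdict(self)


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    return arrs


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical one-way fixed-effects ANOVA (F and p).

    All observations identical across groups gives F = 0, p = 1.
    """
    arrs = _as_groups(groups)
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("ANOVA needs >= 2 groups with n >= 2 each")
    n_total = sum(a.size for a in arrs)
    df = (len(arrs) - 1, n_total - len(arrs))
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, "one-way ANOVA", df=df, n=n_total)
    f, p = stats.f_oneway(*arrs)
    if not np.isfinite(f):  # zero within-group variance, groups differ
        f, p = float("inf"), 0.0
        f = np.finfo(float).max
    return TestResult(float(f), float(p), "one-way ANOVA", df=df, n=n_total)


def tukey_kramer(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> list[dict]:
    """All pairwise Tukey-Kramer comparisons (unequal-n studentized range).

    Returns one dict per pair with the mean difference, p-value and a
    significance verdict at alpha = 0.05.
    """
    arrs = _as_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    pooled = np.concatenate(arrs)
    rows = []
    if np.ptp(pooled) == 0:
        for i in range(len(arrs)):
            for j in range(i + 1, len(arrs)):
                rows.append(
                    {"a": labels[i], "b": labels[j], "mean_diff": 0.0,
                     "p_value": 1.0, "significant": False}
                )
        return rows
    res = stats.tukey_hsd(*arrs)
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "a": labels[i],
                    "b": labels[j],
                    "mean_diff": float(np.mean(arrs[i]) - np.mean(arrs[j])),
                    "p_value": p,
                    "significant": p < 0.05,
                }
            )
    return rows


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction and chi-square p-value."""
    arrs = _as_groups(groups)
    if len(arrs) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, "Kruskal-Wallis", df=len(arrs) - 1, n=n_total)
    h, p = stats.kruskal(*arrs)
    return TestResult(float(h), float(p), "Kruskal-Wallis", df=len(arrs) - 1,
                      n=n_total)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U; exact enumeration for small samples (n <= 8 each,
    no ties), normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult(float(a.size * b.size / 2), 1.0, "Mann-Whitney U",
                          sidedness="two" if alternative == "two-sided" else "one",
                          n=pooled.size)
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and a.size <= 8 and b.size <= 8) else "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(
        float(u), float(p), f"Mann-Whitney U ({method})",
        sidedness="two" if alternative == "two-sided" else "one", n=pooled.size,
    )


def median_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Mood's median test: 2x2 chi-square of counts above/below the pooled
    median (ties at the median dropped, no continuity correction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, "median test", df=1, n=pooled.size)
    grand = np.median(pooled)
    table = np.array(
        [
            [np.sum(a > grand), np.sum(b > grand)],
            [np.sum(a < grand), np.sum(b < grand)],
        ],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return TestResult(0.0, 1.0, "median test", df=1, n=pooled.size)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(p), "median test", df=1, n=pooled.size)


def chi2_contingency(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on an r x c count table, df = (r-1)(c-1).

    No continuity correction by default.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: all-zero row or column")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=correction)
    return TestResult(float(chi2), float(p), "Pearson chi-square", df=int(df),
                      n=int(table.sum()))


def binom_exact(k: int, n: int, p0: float = 0.5,
                alternative: str = "greater") -> TestResult:
    """Exact binomial test by tail summation of the binomial pmf.

    Two-sided p sums all outcomes whose pmf <= pmf(k).
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("need 0 < p0 < 1")
    res = stats.binomtest(k, n, p0, alternative=alternative)
    sided = "two" if alternative == "two-sided" else "one"
    return TestResult(float(k), float(res.pvalue), "exact binomial",
                      sidedness=sided, n=n)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (optional, for association tables)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
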