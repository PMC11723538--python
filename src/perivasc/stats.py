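"""Statistical procedures used throughout the pipeline.

Every routine here is implemented from its definition — rank statistics,
exact small-sample null distributions, the Benjamini–Hochberg step-up and
the chi-square independence decomposition — so each can be verified against
brute-force enumeration in the test suite.  Only distribution functions
(Student t, normal, chi-square CDFs) come from :mod:`scipy.stats`.

Conventions
-----------
* All tests default to two-sided p-values; two-sided p = 2 * min(one-sided)
  capped at 1 for the exact discrete nulls.
* Rank tests use midranks for ties.
* Exact nulls are used below configurable sample-size cutoffs (the study
  sizes this pipeline targets, n ~ 10, sit squarely in exact territory);
  above them, normal approximations with tie and continuity corrections.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm_dist
from scipy.stats import rankdata
from scipy.stats import t as _t_dist

__all__ = [
    "TestResult",
    "ContingencyResult",
    "welch_t_test",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "spearman",
    "bh_adjust",
    "chi_square_independence",
]

# exact-null cutoffs (configurable per call)
RANK_SUM_EXACT_MAX_N = 12      # total n for exact rank-sum enumeration
SIGNED_RANK_EXACT_MAX_N = 25   # n of nonzero diffs for exact signed-rank null
SPEARMAN_EXACT_MAX_N = 8       # n for full-permutation Spearman p


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    two_sided: bool = True
    df: float | None = None
    n: int | None = None
    estimate: float | None = None   # e.g. rho for spearman
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "two_sided": self.two_sided,
            "df": self.df,
            "n": self.n,
            "estimate": self.estimate,
            "note": self.note,
        }


@dataclass
class ContingencyResult:
    """Chi-square test of independence with its Pearson-residual decomposition."""

    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float
    pearson_residuals: np.ndarray
    contributions: np.ndarray       # r_ij^2 / chi2; all-zero (flagged) when chi2 == 0
    degenerate: bool = False
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "method": "chi_square",
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "observed": self.observed.tolist(),
            "expected": self.expected.tolist(),
            "pearson_residuals": self.pearson_residuals.tolist(),
            "contributions": self.contributions.tolist(),
            "degenerate": self.degenerate,
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
        }


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def welch_t_test(a, b, two_sided: bool = True) -> TestResult:
    """Unpaired t-test with Welch's correction for unequal variances.

    t = (mean(a) - mean(b)) / sqrt(s_a^2/n_a + s_b^2/n_b), with the
    Welch–Satterthwaite degrees of freedom.
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires at least 2 observations per group")
    na, nb = a.size, b.size
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = a.mean() - b.mean()
    denom2 = va / na + vb / nb
    if denom2 == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, "welch_t", two_sided, df=float(na + nb - 2),
                              n=na + nb, note="zero variance in both groups, equal means")
        t = math.inf if diff > 0 else -math.inf
        return TestResult(t, 0.0, "welch_t", two_sided, df=float(na + nb - 2),
                          n=na + nb, note="zero variance in both groups, unequal means")
    t = diff / math.sqrt(denom2)
    df = denom2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    if two_sided:
        p = 2.0 * _t_dist.sf(abs(t), df)
    else:
        p = _t_dist.sf(t, df)
    return TestResult(float(t), float(min(p, 1.0)), "welch_t", two_sided,
                      df=float(df), n=na + nb)


def _rank_sum_exact_p(ranks_a_sum: float, na: int, n: int) -> float:
    """Exact two-sided p for the rank-sum statistic (no ties): enumerate all
    C(n, na) assignments of ranks 1..n to group a."""
    lo = 0
    hi = 0
    total = 0
    target = ranks_a_sum
    for combo in itertools.combinations(range(1, n + 1), na):
        s = sum(combo)
        total += 1
        if s <= target + 1e-9:
            lo += 1
        if s >= target - 1e-9:
            hi += 1
    p = 2.0 * min(lo, hi) / total
    return min(p, 1.0)


def wilcoxon_rank_sum(a, b, two_sided: bool = True,
                      exact_max_n: int = RANK_SUM_EXACT_MAX_N) -> TestResult:
    """Unpaired two-sample Wilcoxon rank-sum (Mann–Whitney) test.

    Midranks for ties.  Exact null by full enumeration when
    n_a + n_b <= ``exact_max_n`` and there are no ties; otherwise a normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if a.size < 1 or b.size < 1:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    na, nb = a.size, b.size
    n = na + nb
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return TestResult(0.0, 1.0, "wilcoxon_rank_sum", two_sided, n=n,
                          note="all values identical")
    ranks = rankdata(combined)
    w = float(ranks[:na].sum())
    has_ties = np.unique(combined).size < n

    if n <= exact_max_n and not has_ties:
        p = _rank_sum_exact_p(w, na, n)
        if not two_sided:
            # one-sided: P(W >= w) under the null
            hi = sum(1 for c in itertools.combinations(range(1, n + 1), na)
                     if sum(c) >= w - 1e-9)
            p = hi / math.comb(n, na)
        return TestResult(w, float(p), "wilcoxon_rank_sum", two_sided, n=n,
                          note="exact")

    mean_w = na * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var_w = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return TestResult(w, 1.0, "wilcoxon_rank_sum", two_sided, n=n,
                          note="degenerate variance")
    # continuity correction toward the mean
    z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / math.sqrt(var_w)
    p = 2.0 * _norm_dist.sf(abs(z)) if two_sided else _norm_dist.sf(z)
    return TestResult(w, float(min(p, 1.0)), "wilcoxon_rank_sum", two_sided,
                      n=n, note="normal approximation")


def _signed_rank_null_counts(scaled_ranks: np.ndarray) -> np.ndarray:
    """Distribution of W+ over all sign assignments.

    ``scaled_ranks`` are 2*midranks (integers even with midrank ties).
    Returns counts[s] = number of sign vectors with W+ (on the scaled
    integer grid) equal to s.
    """
    total = int(scaled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(diffs, two_sided: bool = True,
                         exact_max_n: int = SIGNED_RANK_EXACT_MAX_N) -> TestResult:
    """Paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped (noted in the result).  Exact permutation
    null (over all 2^n sign assignments, computed by convolution so midrank
    ties are handled exactly) for n < ``exact_max_n``; otherwise a normal
    approximation with tie-corrected variance.
    """
    d = _as_1d(diffs, "diffs")
    n_zero = int(np.sum(d == 0.0))
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", two_sided, n=0,
                          note=f"all {n_zero} differences zero")
    note = f"{n_zero} zero differences dropped; " if n_zero else ""
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n < exact_max_n:
        scaled = np.rint(2.0 * ranks).astype(int)
        counts = _signed_rank_null_counts(scaled)
        total = counts.sum()
        s_obs = int(round(2.0 * w_plus))
        p_le = counts[: s_obs + 1].sum() / total
        p_ge = counts[s_obs:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge)) if two_sided else p_ge
        return TestResult(w_plus, float(p), "wilcoxon_signed_rank", two_sided,
                          n=n, note=note + "exact")

    mean_w = n * (n + 1) / 4.0
    var_w = float(np.sum(ranks ** 2)) / 4.0      # tie-corrected via midranks
    z = (w_plus - mean_w - 0.5 * np.sign(w_plus - mean_w)) / math.sqrt(var_w)
    p = 2.0 * _norm_dist.sf(abs(z)) if two_sided else _norm_dist.sf(z)
    return TestResult(w_plus, float(min(p, 1.0)), "wilcoxon_signed_rank",
                      two_sided, n=n, note=note + "normal approximation")


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return 0.0
    return float(xc @ yc) / denom


def spearman(x, y, two_sided: bool = True,
             exact_max_n: int = SPEARMAN_EXACT_MAX_N) -> TestResult:
    """Spearman rank correlation: Pearson correlation of midranks.

    p by full permutation enumeration for n <= ``exact_max_n``, else the
    t approximation with n - 2 degrees of freedom.  Constant input yields
    rho = 0 by convention, with a warning.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input to spearman; rho set to 0 by convention")
        return TestResult(0.0, 1.0, "spearman", two_sided, n=n, estimate=0.0,
                          note="constant input")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = _pearson_r(rx, ry)

    if n <= exact_max_n:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            r = _pearson_r(rx, np.asarray(perm))
            total += 1
            if two_sided:
                if abs(r) >= target:
                    count += 1
            else:
                if r >= rho - 1e-12:
                    count += 1
        return TestResult(rho, count / total, "spearman", two_sided, n=n,
                          estimate=rho, note="exact permutation")

    if abs(rho) >= 1.0:
        return TestResult(rho, 0.0, "spearman", two_sided, n=n, estimate=rho,
                          note="|rho| = 1")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * _t_dist.sf(abs(t), n - 2) if two_sided else _t_dist.sf(t, n - 2)
    return TestResult(rho, float(min(p, 1.0)), "spearman", two_sided, n=n,
                      df=float(n - 2), estimate=rho, note="t approximation")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Sort ascending, q_(i) = min_{j >= i} p_(j) * m / j clipped at 1, then
    restore the input order.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def chi_square_independence(table, row_labels=None, col_labels=None) -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    E_ij = row_i * col_j / N; chi2 = sum (O-E)^2 / E; df = (r-1)(c-1).
    No continuity correction (the r x c case; some packages default to
    Yates for 2 x 2 — deliberately not applied here).  Pearson residuals
    (O-E)/sqrt(E) and their squared shares of chi2 ("contributions",
    summing to 1 when chi2 > 0) are returned for association plots.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(obs < 0) or not np.allclose(obs, np.rint(obs)):
        raise ValueError("table must hold non-negative integer counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all row and column margins must be positive")
    n = obs.sum()
    expected = np.outer(row, col) / n
    resid = (obs - expected) / np.sqrt(expected)
    stat = float(np.sum(resid ** 2))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_chi2_dist.sf(stat, df))
    if stat > 0:
        contrib = resid ** 2 / stat
        degenerate = False
    else:
        contrib = np.zeros_like(resid)
        degenerate = True
    return ContingencyResult(
        observed=obs, expected=expected, statistic=stat, df=df, p_value=p,
        pearson_residuals=resid, contributions=contrib, degenerate=degenerate,
        row_labels=list(row_labels) if row_labels is not None else [],
        col_labels=list(col_labels) if col_labels is not None else [],
    )
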