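"""The statistical battery: paired rank test, Fisher's method, bootstrap
CIs, Cohen's d, sign and rank-sum tests.

Conventions follow the R toolchain this analysis style comes from:
Wilcoxon zeros are discarded (classic zero-discard policy, R's
default; Pratt's treatment is available via ``zero_method``), bootstrap
CIs are percentile intervals of the resampled mean with B = 500, and
Cohen's d carries a normal-theory CI using
``Var(d) = (n_a+n_b)/(n_a*n_b) + d^2 / (2(n_a+n_b))`` with a
t(n_a+n_b-2) critical value, which reproduces compute.es-style wide
intervals at small group counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class CohortResult:
    """Flank-vs-core summary for one tumour cohort."""

    cohort: str
    n_tumours: int
    mean_rate: dict = field(default_factory=dict)     # role group -> pooled rate
    wilcoxon_p: float = float("nan")
    density: dict = field(default_factory=dict)       # role group -> DensityEstimate
    depletion: float = float("nan")
    flank5_rate: float = float("nan")
    flank3_rate: float = float("nan")
    n_flank5_lower: int = 0
    n_informative_53: int = 0
    sign_test_p: float = float("nan")


@dataclass
class CombinedResult:
    """Fisher's-method combination over cohorts plus pooled effect size."""

    chi2_stat: float
    df: int
    combined_p: float
    cohens_d: float = float("nan")
    d_ci: tuple = (float("nan"), float("nan"))
    depletion: float = float("nan")


def wilcoxon_signed_rank(x, y, zero_method: str = "wilcox") -> float:
    """Two-sided paired signed-rank p-value.

    Zero differences are discarded (``zero_method='wilcox'``) or kept
    per Pratt (``'pratt'``). Exact null distribution when the retained
    differences are <= 25 and untied in absolute value; tie-corrected
    normal approximation otherwise. All-zero differences return p = 1
    by contract.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be equal-length, non-empty")
    d = x - y
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return 1.0
    n = nonzero.size
    tied = len(np.unique(np.abs(nonzero))) < n
    method = "exact" if (n <= 25 and not tied and zero_method == "wilcox") else "approx"
    res = sps.wilcoxon(
        x, y, zero_method=zero_method, correction=False,
        alternative="two-sided", method=method,
    )
    return float(res.pvalue)


def fishers_combined(pvals) -> CombinedResult:
    """Fisher's method: chi2 = -2 sum(ln p), df = 2k, upper-tail p."""
    pvals = list(pvals)
    if not pvals:
        raise ValueError("no p-values to combine")
    for p in pvals:
        if not 0 < p <= 1:
            raise ValueError(
                f"p-value {p} outside (0, 1]; clamp zeros at the machine minimum first"
            )
    chi2 = -2.0 * sum(math.log(p) for p in pvals)
    df = 2 * len(pvals)
    return CombinedResult(chi2_stat=chi2, df=df, combined_p=float(sps.chi2.sf(chi2, df)))


def bootstrap_mean_ci(values, B: int = 500, confidence: float = 0.95, seed: int = 0):
    """Percentile bootstrap CI of the mean: (mean, low, high).

    Deterministic for a given seed; B resamples with replacement.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    means = values[idx].mean(axis=1)
    alpha = 1.0 - confidence
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(values.mean()), float(lo), float(hi)


def cohens_d(a, b, confidence: float = 0.95):
    """Standardized mean difference (pooled, unbiased variances) with CI.

    Returns (d, ci_low, ci_high).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = (a.mean() - b.mean()) / pooled
    var_d = (na + nb) / (na * nb) + d * d / (2 * (na + nb))
    half = sps.t.ppf(1 - (1 - confidence) / 2, na + nb - 2) * math.sqrt(var_d)
    return float(d), float(d - half), float(d + half)


def binomial_sign_test(k: int, n: int, p0: float = 0.5, sided: str = "one") -> float:
    """Exact binomial tail probability.

    One-sided: P[X >= k]; two-sided: doubled smaller tail, capped at 1.
    """
    if not 0 < p0 < 1:
        raise ValueError(f"p0 {p0} outside (0, 1)")
    if not 0 <= k <= n:
        raise ValueError(f"k {k} outside [0, {n}]")
    upper = float(sps.binom.sf(k - 1, n, p0))
    if sided == "one":
        return upper
    if sided != "two":
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    lower = float(sps.binom.cdf(k, n, p0))
    return min(1.0, 2.0 * min(upper, lower))


def _mwu_exact_enumeration(a, b) -> float:
    """Tie-aware exact two-sided Mann-Whitney p by enumerating all
    assignments of the pooled values to the two groups."""
    pooled = list(a) + list(b)
    na = len(a)
    idx_all = range(len(pooled))

    def u_stat(group_a_idx):
        set_a = set(group_a_idx)
        u = 0.0
        for i in group_a_idx:
            for j in idx_all:
                if j in set_a:
                    continue
                if pooled[i] > pooled[j]:
                    u += 1.0
                elif pooled[i] == pooled[j]:
                    u += 0.5
        return u

    u_obs = u_stat(range(na))
    us = [u_stat(comb) for comb in itertools.combinations(idx_all, na)]
    total = len(us)
    ge = sum(1 for u in us if u >= u_obs) / total
    le = sum(1 for u in us if u <= u_obs) / total
    return min(1.0, 2.0 * min(ge, le))


def mann_whitney_u(a, b, exact_limit: int = 14) -> float:
    """Two-sided rank-sum p-value.

    Exact (tie-aware, by exhaustive enumeration) when the pooled sample
    is small; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size + b.size <= exact_limit:
        return _mwu_exact_enumeration(a.tolist(), b.tolist())
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)
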