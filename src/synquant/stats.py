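"""Statistical layer: permutation and KS tests, Bonferroni–Holm
correction, and summary-statistic effect size / power.

Group endpoints (one value per animal) are compared with a two-tailed
two-sample permutation test on the difference of means (default 10^4
permutations; exhaustive enumeration is used automatically when the
number of distinct group splits is no larger than the permutation
budget).  Distributions of per-synapse fluorescence are compared with
the two-sample Kolmogorov–Smirnov test.  Families of p-values are
adjusted by the Bonferroni–Holm step-down procedure.  Cohen's d and
noncentral-t power are computed from printed summary statistics
(mean ± sem, n) so published designs can be checked without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "TestResult",
    "permutation_test",
    "ks_two_sample",
    "holm_adjust",
    "benjamini_hochberg_adjust",
    "cohens_d_from_summary",
    "power_two_sample_t",
    "compare_groups",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    p_adjusted: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def permutation_test(a, b, n_perm: int = 10_000, seed: int | None = None) -> TestResult:
    """Two-tailed two-sample permutation test on the difference of means.

    Group labels are permuted uniformly without replacement.  When the
    number of distinct splits C(n_a+n_b, n_a) is at most ``n_perm`` all
    splits are enumerated and the p-value is the exact fraction of splits
    with |mean difference| at least the observed one (the identity split
    included).  Otherwise ``n_perm`` random permutations are drawn and
    the add-one–smoothed Monte-Carlo p-value
    (1 + #{|stat*| >= |stat|}) / (n_perm + 1) is reported, which avoids
    p = 0.  Deterministic for a fixed seed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    na, n = len(a), len(a) + len(b)
    total = comb(n, na)
    tol = 1e-12 * max(1.0, abs(observed))

    if total <= n_perm:
        idx = np.fromiter(
            (i for c in combinations(range(n), na) for i in c),
            dtype=np.intp, count=total * na).reshape(total, na)
        stats = _split_stats(pooled, idx, na, n)
        hits = int(np.sum(np.abs(stats) >= abs(observed) - tol))
        return TestResult(statistic=float(observed), p_value=hits / total,
                          method="permutation-exact", n_permutations=total,
                          seed=seed)
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 2000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((m, n)), axis=1)[:, :na]
        stats = _split_stats(pooled, perms, na, n)
        hits += int(np.sum(np.abs(stats) >= abs(observed) - tol))
        done += m
    p = (1 + hits) / (n_perm + 1)
    return TestResult(statistic=float(observed), p_value=p,
                      method="permutation-mc", n_permutations=n_perm, seed=seed)


def _split_stats(pooled: np.ndarray, idx_a: np.ndarray, na: int, n: int) -> np.ndarray:
    """Difference of means for each row of group-A indices."""
    total_sum = pooled.sum()
    sum_a = pooled[idx_a].sum(axis=1)
    mean_a = sum_a / na
    mean_b = (total_sum - sum_a) / (n - na)
    return mean_a - mean_b


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    res = sstats.ks_2samp(a, b, method="asymp")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="ks-2samp")


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni–Holm step-down adjustment, returned in input order.

    Sorted ascending, the i-th smallest raw p is multiplied by
    (m - i + 1); running maxima enforce monotonicity and values are
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def benjamini_hochberg_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg FDR step-up adjustment (not the default
    multiple-comparison rule here; provided for completeness)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


def cohens_d_from_summary(mean1: float, sem1: float, n1: int,
                          mean2: float, sem2: float, n2: int) -> float:
    """Cohen's d from printed group summaries (mean ± sem, n).

    Group SDs are recovered as sem * sqrt(n); the pooling uses the
    equal-weight form sqrt((sd1^2 + sd2^2) / 2), identical to df-weighted
    pooling when group sizes are equal.
    """
    if sem1 < 0 or sem2 < 0:
        raise ValueError("sems must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sd1 = sem1 * np.sqrt(n1)
    sd2 = sem2 * np.sqrt(n2)
    pooled = np.sqrt((sd1 ** 2 + sd2 ** 2) / 2)
    if pooled == 0:
        raise ValueError("both group SDs are zero; effect size undefined")
    return float(abs(mean2 - mean1) / pooled)


def power_two_sample_t(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Power of the two-tailed two-sample t-test via the noncentral t.

    df = 2n - 2, noncentrality = d * sqrt(n / 2).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2)
    tcrit = sstats.t.ppf(1 - alpha / 2, df)
    power = (1 - sstats.nct.cdf(tcrit, df, nc)) + sstats.nct.cdf(-tcrit, df, nc)
    return float(power)


def compare_groups(values, group_labels, n_perm: int = 10_000,
                   seed: int | None = None) -> pd.DataFrame:
    """All pairwise permutation comparisons with Holm-adjusted p-values
    and Cohen's d, one row per group pair."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = list(dict.fromkeys(group_labels.tolist()))
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            a = values[group_labels == ga]
            b = values[group_labels == gb]
            res = permutation_test(a, b, n_perm=n_perm, seed=seed)
            d = cohens_d_from_summary(a.mean(), a.std(ddof=1) / np.sqrt(len(a)), len(a),
                                      b.mean(), b.std(ddof=1) / np.sqrt(len(b)), len(b))
            rows.append({"group_a": ga, "group_b": gb,
                         "mean_a": a.mean(), "mean_b": b.mean(),
                         "statistic": res.statistic, "p_raw": res.p_value,
                         "cohens_d": d, "method": res.method})
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_holm"] = holm_adjust(frame["p_raw"].to_numpy())
    return frame
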