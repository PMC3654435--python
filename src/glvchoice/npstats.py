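"""Rank-based tests with exact small-sample enumeration.

All group comparisons in the toolkit are nonparametric: Mann-Whitney U for
two independent samples, the Wilcoxon signed-rank test for paired or
one-sample comparisons (e.g. activation ratios against 1), Kruskal-Wallis
for several groups and Dunn's post-hoc pairwise test.

For small samples the two-sided p-value is exact, obtained by enumerating
all group labelings (U) or all 2^n sign patterns (signed rank) of the
observed data, so ties are handled exactly by construction.  Larger
samples use the tie-corrected normal (or chi-square) approximation.
Exact two-sided p doubles the smaller tail mass, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "dunn_posthoc",
    "compact_letter_display",
]

EXACT_U_MAX_N = 12  # enumerate C(n+m, n) labelings when n + m <= this
EXACT_W_MAX_N = 15  # enumerate 2^n sign patterns when n <= this


@dataclass
class TestResult:
    """Outcome of one nonparametric test."""

    method: str
    statistic: float
    p_two_sided: float
    mode: str  # "exact" | "approx"
    sample_sizes: tuple[int, ...]
    adjusted_p: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.p_two_sided <= 1:
            raise ValueError("p-value must be in (0, 1]")


def _rankdata(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _two_sided_from_tail(lower_mass: float, upper_mass: float) -> float:
    return min(2.0 * min(lower_mass, upper_mass), 1.0)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(ranks_x: np.ndarray, n: int) -> float:
    """U for the first sample from its pooled ranks."""
    return float(ranks_x.sum() - n * (n + 1) / 2.0)


def mann_whitney_u(x, y, method: str = "auto") -> TestResult:
    """Two-sample rank-sum test.

    Exact mode enumerates all C(n+m, n) assignments of the pooled observed
    values to the two groups when n + m <= 12 (a permutation null that is
    exact under ties as well); otherwise the tie-corrected normal
    approximation with continuity correction applies.  ``method`` forces
    ``"exact"`` or ``"approx"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    u_obs = _u_statistic(ranks[:n], n)
    mu = n * m / 2.0

    use_exact = (n + m <= EXACT_U_MAX_N) if method == "auto" else method == "exact"
    if use_exact:
        idx_all = range(n + m)
        count_le = 0
        count_ge = 0
        total = 0
        for combo in combinations(idx_all, n):
            u = _u_statistic(ranks[list(combo)], n)
            total += 1
            if u <= u_obs + 1e-12:
                count_le += 1
            if u >= u_obs - 1e-12:
                count_ge += 1
        p = _two_sided_from_tail(count_le / total, count_ge / total)
        mode = "exact"
    else:
        big_n = n + m
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / (big_n * (big_n - 1))
        sigma2 = n * m / 12.0 * ((big_n + 1) - tie_term)
        if sigma2 <= 0:
            p, mode = 1.0, "approx"
        else:
            z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / np.sqrt(sigma2)
            p = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
            mode = "approx"
        p = max(p, np.finfo(float).tiny)
    return TestResult(method="mann_whitney_u", statistic=u_obs,
                      p_two_sided=max(p, np.finfo(float).tiny),
                      mode=mode, sample_sizes=(n, m))


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign patterns as a (2^n, n) 0/1 matrix."""
    bits = np.arange(2 ** n, dtype=np.uint32)
    return ((bits[:, None] >> np.arange(n)[None, :]) & 1).astype(float)


def wilcoxon_signed_rank(diffs, mu: float = 0.0, method: str = "auto") -> TestResult:
    """One-sample / paired signed-rank test against center ``mu``.

    Zero (centered) differences are dropped before ranking (Wilcoxon's
    original rule).  Exact mode enumerates all 2^n sign patterns of the
    observed absolute ranks when n <= 15; otherwise the tie-corrected
    normal approximation with continuity correction applies.  The reported
    statistic W is the smaller of the positive and negative rank sums.
    """
    d = np.asarray(diffs, dtype=float) - mu
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    abs_ranks = _rankdata(np.abs(d))
    w_plus = float(abs_ranks[d > 0].sum())
    total = float(abs_ranks.sum())
    w = min(w_plus, total - w_plus)

    use_exact = (n <= EXACT_W_MAX_N) if method == "auto" else method == "exact"
    if use_exact:
        signs = _sign_matrix(n)
        w_plus_all = signs @ abs_ranks
        lower = np.mean(w_plus_all <= w_plus + 1e-9)
        upper = np.mean(w_plus_all >= w_plus - 1e-9)
        p = _two_sided_from_tail(lower, upper)
        mode = "exact"
    else:
        mu_w = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        sigma2 = (n * (n + 1) * (2 * n + 1) / 24.0
                  - np.sum(counts ** 3 - counts) / 48.0)
        z = (w_plus - mu_w - 0.5 * np.sign(w_plus - mu_w)) / np.sqrt(sigma2)
        p = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
        mode = "approx"
    return TestResult(method="wilcoxon_signed_rank", statistic=w,
                      p_two_sided=max(p, np.finfo(float).tiny),
                      mode=mode, sample_sizes=(n,))


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn
# ---------------------------------------------------------------------------

def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) == 0 for g in gs):
        raise ValueError("need at least 2 non-empty groups")
    return gs


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    gs = _check_groups(groups)
    pooled = np.concatenate(gs)
    big_n = len(pooled)
    ranks = _rankdata(pooled)
    h = 0.0
    start = 0
    for g in gs:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts ** 3 - counts) / (big_n ** 3 - big_n)
    if tie_corr <= 0:  # all values identical
        return TestResult(method="kruskal_wallis", statistic=0.0,
                          p_two_sided=1.0, mode="approx",
                          sample_sizes=tuple(len(g) for g in gs))
    h /= tie_corr
    h = max(h, 0.0)
    p = float(sps.chi2.sf(h, df=len(gs) - 1))
    return TestResult(method="kruskal_wallis", statistic=float(h),
                      p_two_sided=max(min(p, 1.0), np.finfo(float).tiny),
                      mode="approx", sample_sizes=tuple(len(g) for g in gs))


def dunn_posthoc(groups, labels: list[str] | None = None,
                 alpha: float = 0.05) -> list[TestResult]:
    """Dunn's pairwise z tests on pooled ranks, Bonferroni adjusted.

    Returns one TestResult per group pair with both the unadjusted and the
    Bonferroni-adjusted two-sided p.  Pair identity and the mean ranks are
    carried in ``extra``.
    """
    gs = _check_groups(groups)
    k = len(gs)
    labels = labels or [f"group{i}" for i in range(k)]
    pooled = np.concatenate(gs)
    big_n = len(pooled)
    ranks = _rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in gs:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (big_n - 1))
    n_pairs = k * (k - 1) // 2
    results = []
    for i, j in combinations(range(k), 2):
        var = (big_n * (big_n + 1) / 12.0 - tie_term) * (1 / len(gs[i]) + 1 / len(gs[j]))
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
        p = max(p, np.finfo(float).tiny)
        adj = min(p * n_pairs, 1.0)
        results.append(TestResult(
            method="dunn", statistic=float(z), p_two_sided=p, mode="approx",
            sample_sizes=(len(gs[i]), len(gs[j])), adjusted_p=adj,
            extra={"pair": (labels[i], labels[j]),
                   "mean_ranks": (float(mean_ranks[i]), float(mean_ranks[j]))}))
    return results


def compact_letter_display(pairwise: list[TestResult],
                           labels: list[str],
                           alpha: float = 0.05) -> dict[str, str]:
    """Assign significance letters: groups sharing a letter do not differ.

    Greedy insert-and-absorb over groups in label order; uses the adjusted
    p-values of a Dunn pairwise result set.
    """
    differ = set()
    for r in pairwise:
        a, b = r.extra["pair"]
        if (r.adjusted_p if r.adjusted_p is not None else r.p_two_sided) < alpha:
            differ.add(frozenset((a, b)))

    letter_sets: list[set[str]] = []
    for lab in labels:
        placed = False
        for s in letter_sets:
            if all(frozenset((lab, other)) not in differ for other in s):
                s.add(lab)
                placed = True
        if not placed:
            letter_sets.append({lab})
    # drop letter sets fully contained in another
    keep = [s for i, s in enumerate(letter_sets)
            if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, s in zip(letters, keep):
        for lab in labels:
            if lab in s:
                out[lab] += letter
    return out
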