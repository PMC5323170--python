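"""Exact statistics used throughout the pipeline.

Three primitives, each implemented from first principles because their exact
conventions are the contract the rest of the package relies on:

* :func:`fisher_exact_two_sided` — the two-sided Fisher exact test under the
  "sum of tables whose point probability does not exceed the observed one"
  convention (the convention R's ``fisher.test`` uses, and the one that
  reproduces published two-tailed p-values such as 0.0121 / 0.0072 / 1.0000
  for cohort-scale 2x2 tables).
* :func:`mann_whitney_u` — the Mann-Whitney U test with midranks, an exact
  permutation path for small samples (ties included in the enumeration), an
  exact null-distribution path for moderate tie-free samples, and a
  tie-corrected normal approximation with continuity correction otherwise.
* :func:`bh_adjust` — Benjamini-Hochberg step-up q-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


class StatsUsageError(ValueError):
    """Raised when a statistical routine is called on invalid input."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Integer 2x2 table; rows are levels of factor 1, columns of factor 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise StatsUsageError(f"cell {name!r} must be an integer, got {v!r}")
            if v < 0:
                raise StatsUsageError(f"cell {name!r} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_two_sided: float
    method: str  # "exact" or "normal_approx"


# relative slack when deciding whether a table's probability "ties" the
# observed one; guards against floating-point noise in the tail sum
_FISHER_TIE_RTOL = 1e-7


def _log_hypergeom_pmf(k: int, r1: int, r2: int, c1: int) -> float:
    """log P(first cell = k) for fixed margins, via log-factorials."""
    n = r1 + r2
    return (
        math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
        + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1) - math.lgamma(r2 - (c1 - k) + 1)
        - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
    )


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value.

    Sums hypergeometric point probabilities over every table with the observed
    margins whose probability is <= the observed table's probability (with a
    1e-7 relative tie tolerance). Computed in log space; clamped to <= 1.

    An all-zero table is degenerate and yields p = 1 with a warning.
    """
    if table.total == 0:
        warnings.warn("all-zero contingency table; p-value is 1 by convention")
        return 1.0
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    log_obs = _log_hypergeom_pmf(table.a, r1, r2, c1)
    cutoff = log_obs + math.log1p(_FISHER_TIE_RTOL)
    p = 0.0
    for k in range(k_lo, k_hi + 1):
        lp = _log_hypergeom_pmf(k, r1, r2, c1)
        if lp <= cutoff:
            p += math.exp(lp)
    return min(1.0, p)


def _u_from_ranks(ranks: np.ndarray, idx_x: Sequence[int], n1: int) -> float:
    rank_sum = float(np.sum(ranks[list(idx_x)]))
    return rank_sum - n1 * (n1 + 1) / 2.0


def _exact_u_counts_no_ties(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U without ties: counts[u] = #subsets with U = u.

    Coefficients of the Gaussian binomial [n1+n2 choose n1]_q, built with the
    recurrence [m k]_q = q^(m-k) [m-1 k-1]_q + [m-1 k]_q.
    """
    k = min(n1, n2)  # distribution is symmetric in (n1, n2)
    m_total = n1 + n2
    # polys[j] holds [m j]_q as an integer coefficient array
    polys: list[np.ndarray] = [np.array([1], dtype=object)]
    for j in range(1, k + 1):
        polys.append(np.zeros(0, dtype=object))
    for m in range(1, m_total + 1):
        for j in range(min(m, k), 0, -1):
            if j == m:
                polys[j] = np.array([1], dtype=object)
                continue
            shifted = np.concatenate(
                [np.zeros(m - j, dtype=object), polys[j - 1]]
            )
            size = max(len(shifted), len(polys[j]))
            out = np.zeros(size, dtype=object)
            out[: len(shifted)] += shifted
            out[: len(polys[j])] += polys[j]
            polys[j] = out
    counts = np.zeros(n1 * n2 + 1, dtype=object)
    counts[: len(polys[k])] = polys[k]
    return counts


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    *,
    exact_limit: int = 12,
    exact_max_product: int = 10_000,
) -> MannWhitneyResult:
    """Mann-Whitney U test, two-sided.

    The U statistic is computed from midrank sums (ties get average ranks).
    The p-value path depends on the data:

    * ``n1 + n2 <= exact_limit`` — exact, by full enumeration of all
      C(n1+n2, n1) group labelings of the pooled sample (valid with ties);
    * no ties and ``n1 * n2 <= exact_max_product`` — exact, from the classical
      null distribution of U (what R's ``wilcox.test`` does for n < 50);
    * otherwise — normal approximation with tie-corrected variance and a 0.5
      continuity correction.

    The two-sided p is ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise StatsUsageError("both samples must be non-empty")
    pooled = np.asarray(x + y, dtype=float)
    ranks = rankdata(pooled)
    u_obs = _u_from_ranks(ranks, range(n1), n1)
    n = n1 + n2

    if n <= exact_limit:
        total = math.comb(n, n1)
        n_le = n_ge = 0
        for idx in combinations(range(n), n1):
            u = _u_from_ranks(ranks, idx, n1)
            if u <= u_obs + 1e-9:
                n_le += 1
            if u >= u_obs - 1e-9:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return MannWhitneyResult(u_obs, max(p, 1.0 / total), "exact")

    has_ties = len(np.unique(pooled)) < n
    if not has_ties and n1 * n2 <= exact_max_product:
        counts = _exact_u_counts_no_ties(n1, n2)
        total = int(counts.sum())
        u_int = int(round(u_obs))
        n_le = int(counts[: u_int + 1].sum())
        n_ge = int(counts[u_int:].sum())
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return MannWhitneyResult(u_obs, max(p, 1.0 / total), "exact")

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every observation identical
        return MannWhitneyResult(u_obs, 1.0, "normal_approx")
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, math.erfc(z / math.sqrt(2.0)))
    return MannWhitneyResult(u_obs, p, "normal_approx")


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q(i) = min_{j >= i} p(j) * m / j`` over the ascending-sorted p-values,
    capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise StatsUsageError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q.tolist()
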