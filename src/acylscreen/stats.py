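"""Supporting statistics for the acyl-amine pipeline, from first principles.

Mann-Whitney U (exact labeling enumeration for small samples, tie-corrected
normal approximation otherwise), Benjamini-Hochberg step-up FDR (Bonferroni
available), the hypergeometric survival function for pathway enrichment in
exact integer arithmetic, Spearman rank correlation (t-approximation or
exact permutation), the trapezoidal area under a glucose curve, a relative
growth ratio, and the prevalence pre-filter for differential abundance.

Independent library implementations (scipy.stats) are used in the test suite
as cross-checks, never as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb, erfc, sqrt
from typing import Sequence

import numpy as np
from scipy.stats import t as _t_dist

__all__ = [
    "TestResult",
    "EnrichmentInput",
    "mann_whitney_u",
    "bh_fdr",
    "adjust_pvalues",
    "hypergeom_enrichment",
    "spearman",
    "trapezoid_auc",
    "relative_growth",
    "prevalence_filter",
]

EXACT_MWU_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its p-value (and optional FDR q-value)."""

    statistic: float
    p_value: float
    q_value: float | None = None


@dataclass(frozen=True)
class EnrichmentInput:
    """Hypergeometric 2x2 input for pathway over-representation.

    N metabolites annotated in total, K of them in the sub-pathway, n
    associated with the taxon, k associated metabolites inside the pathway.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self):
        if min(self.N, self.K, self.n, self.k) < 0:
            raise ValueError("all counts must be nonnegative")
        if self.K > self.N or self.n > self.N:
            raise ValueError("K and n cannot exceed N")
        if self.k > min(self.n, self.K):
            raise ValueError("k cannot exceed min(n, K)")


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _u_from_ranks(rank_sum_x: float, n1: int) -> float:
    return rank_sum_x - n1 * (n1 + 1) / 2


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U counts pairs with x_i > y_j plus half the ties. ``mode`` is ``exact``
    (full enumeration of labelings), ``approx`` (tie-corrected normal
    approximation with continuity correction), or ``auto`` (exact when
    n1 + n2 <= 12). The two-sided p doubles the smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = _u_from_ranks(ranks[:n1].sum(), n1)

    if mode == "exact" or (mode == "auto" and n <= EXACT_MWU_MAX_N):
        # Enumerate every assignment of n1 pooled values to group x.
        u_values = []
        for subset in combinations(range(n), n1):
            u_values.append(_u_from_ranks(ranks[list(subset)].sum(), n1))
        u_values = np.array(u_values)
        eps = 1e-9
        p_low = np.mean(u_values <= u_obs + eps)
        p_high = np.mean(u_values >= u_obs - eps)
        p = min(1.0, 2 * min(p_low, p_high))
        return TestResult(statistic=float(u_obs), p_value=float(p))

    mean_u = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:  # all values identical
        return TestResult(statistic=float(u_obs), p_value=1.0)
    z = (abs(u_obs - mean_u) - 0.5) / sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, erfc(z / sqrt(2)))
    return TestResult(statistic=float(u_obs), p_value=float(p))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def adjust_pvalues(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: ``bh`` (default) or ``bonferroni``."""
    if method == "bh":
        return bh_fdr(p_values)
    if method == "bonferroni":
        p = np.asarray(p_values, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown method {method!r}")


def hypergeom_enrichment(e: EnrichmentInput) -> TestResult:
    """Over-representation p-value P(X >= k), X ~ Hypergeom(N, K, n).

    Computed as an exact ratio of integer binomial sums, so small inputs are
    exact to machine precision.
    """
    upper = min(e.n, e.K)
    numerator = sum(
        comb(e.K, i) * comb(e.N - e.K, e.n - i)
        for i in range(e.k, upper + 1)
        if e.n - i <= e.N - e.K
    )
    denominator = comb(e.N, e.n)
    return TestResult(statistic=float(e.k), p_value=numerator / denominator)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(a @ b) / denom


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation: Pearson correlation of midranks.

    p-value by t-approximation for n >= 10, exact permutation of the y ranks
    otherwise. Constant input vectors are rejected (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    rx, ry = _midranks(x), _midranks(y)
    rho = _pearson(rx, ry)
    n = x.size
    if n >= 10:
        if abs(rho) >= 1.0:
            return TestResult(statistic=rho, p_value=0.0)
        t_stat = rho * sqrt((n - 2) / (1 - rho * rho))
        p = 2 * float(_t_dist.sf(abs(t_stat), n - 2))
        return TestResult(statistic=rho, p_value=min(1.0, p))
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in permutations(ry):
        total += 1
        if abs(_pearson(rx, np.array(perm))) >= target:
            count += 1
    return TestResult(statistic=rho, p_value=count / total)


def trapezoid_auc(times: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoidal area under a curve (e.g. OGTT glucose vs minutes)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size or t.size < 2:
        raise ValueError("need >= 2 paired (time, value) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def relative_growth(
    od_condition: float | Sequence[float], od_reference: float | Sequence[float]
) -> float:
    """Growth ratio: OD600 with supplementation over OD600 without.

    Sequence inputs (e.g. triplicates) are averaged before taking the ratio.
    """
    cond = float(np.mean(np.asarray(od_condition, dtype=float)))
    ref = float(np.mean(np.asarray(od_reference, dtype=float)))
    if ref <= 0:
        raise ValueError("reference OD must be positive")
    return cond / ref


def prevalence_filter(abundance, min_prevalence: float = 0.20):
    """Drop features detected in fewer than ``min_prevalence`` of samples.

    ``abundance`` is a features x samples DataFrame (or 2-D array); a feature
    is detected in a sample when its value is > 0. The retained threshold is
    inclusive (prevalence exactly at the cutoff is kept).
    """
    import pandas as pd

    frame = pd.DataFrame(abundance)
    prevalence = (frame > 0).mean(axis=1)
    return frame.loc[prevalence >= min_prevalence]
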