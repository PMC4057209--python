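"""Paired nonparametric cohort statistics.

Cerebral haemodynamic metrics are typically non-normal in small cohorts,
so paired contrasts (intervention vs normoxia, baseline vs endotoxin)
use Wilcoxon's signed-rank test with an exact permutation null for small
n, Holm's sequential (step-down) Bonferroni correction within each
family of comparisons, and median/interquartile-range summaries.

The exact null distribution is computed by dynamic programming over all
2^n sign assignments of the mid-ranks of |differences| (ties produce
half-integer ranks, handled by doubling), which remains exact in the
presence of ties — unlike the classical table-based exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateSampleError, ValidationError

#: Largest n for which the exact permutation null is enumerated.
EXACT_N_MAX = 20


@dataclass(frozen=True)
class PairedSample:
    """Values of one metric for the same subjects under two conditions."""

    labels: tuple
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if not (len(self.labels) == self.a.size == self.b.size):
            raise ValidationError("labels and both value arrays must have equal length")
        if self.a.size < 1:
            raise ValidationError("paired sample is empty")


@dataclass(frozen=True)
class TestResult:
    """Wilcoxon signed-rank outcome; ``p_adjusted`` is filled in by Holm."""

    statistic: float  # W = sum of positive ranks
    p_raw: float
    method: str  # 'exact' or 'normal-approximation'
    n_effective: int  # pairs remaining after zero-difference removal
    p_adjusted: Optional[float] = None


def _exact_signed_rank_p(ranks: np.ndarray, w: float, alternative: str) -> float:
    # DP over the distribution of W = sum of positive ranks under random signs.
    # Mid-ranks are half-integers at worst; double them to get integers.
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    # counts[s] = number of sign assignments with doubled rank-sum s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    counts /= 2.0 ** len(r2)
    w2 = int(np.rint(2 * w))
    p_less = float(counts[: w2 + 1].sum())
    p_greater = float(counts[w2:].sum())
    if alternative == "less":
        return min(1.0, p_less)
    if alternative == "greater":
        return min(1.0, p_greater)
    return min(1.0, 2.0 * min(p_less, p_greater))


def _normal_approx_p(d: np.ndarray, ranks: np.ndarray, w: float, alternative: str) -> float:
    from scipy.stats import norm

    n = d.size
    mn = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on the ranks of |d|
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var)
    # continuity correction toward the mean
    if alternative == "greater":
        return float(norm.sf((w - mn - 0.5) / sd))
    if alternative == "less":
        return float(norm.cdf((w - mn + 0.5) / sd))
    z = (w - mn - 0.5 * np.sign(w - mn)) / sd
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_signed_rank(
    sample: PairedSample, alternative: str = "two-sided"
) -> TestResult:
    """Paired Wilcoxon signed-rank test on differences ``a - b``.

    Zero differences are dropped before ranking (Wilcoxon's original
    convention); ties among |differences| receive mid-ranks. For
    n <= 20 the p-value is exact over all 2^n sign assignments; larger
    samples use the normal approximation with tie and continuity
    corrections. ``alternative='greater'`` tests for a > b.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    d = sample.a - sample.b
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateSampleError(
            "all paired differences are zero; the signed-rank test is undefined"
        )
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if d.size <= EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w, alternative)
        method = "exact"
    else:
        p = _normal_approx_p(d, ranks, w, alternative)
        method = "normal-approximation"
    return TestResult(statistic=w, p_raw=p, method=method, n_effective=int(d.size))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in the input order.

    Sorted ascending, the i-th smallest raw p is multiplied by
    (m - i + 1) and running maxima enforce monotonicity; results are
    capped at 1. Dominates no correction and is dominated by plain
    Bonferroni: p_raw <= p_holm <= min(1, m * p_raw).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles (linear interpolation between order statistics)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValidationError("cannot summarise an empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3)
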