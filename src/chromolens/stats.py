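"""Exact 2x2 association testing built on the hypergeometric distribution.

The two-sided Fisher p-value follows the minimum-likelihood rule: it sums the
point probabilities of every table with the observed margins whose point
probability does not exceed the observed one (within a small relative
tolerance for floating-point ties).  This is the rule used by the common
exact-test calculators.  All binomial coefficients are evaluated in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .core import ValidationError

#: relative tolerance when comparing point probabilities for the two-sided sum
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = group, columns = lesion / no lesion."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be nonnegative")
        if self.total == 0:
            raise ValidationError("contingency table is all zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    p_one_sided_greater: float
    odds_ratio: float
    table: ContingencyTable2x2 | None = None


def _log_comb(n, k):
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_point_prob(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n).

    Returns the probability of drawing exactly ``k`` marked items in ``n``
    draws without replacement from ``N`` items of which ``K`` are marked.
    ``k`` outside the support returns 0.0 (not an error).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    logp = _log_comb(K, k) + _log_comb(N - K, n - k) - _log_comb(N, n)
    return float(np.exp(logp))


def _support_pmf(N: int, K: int, n: int):
    """Support and pmf of Hypergeometric(N, K, n), vectorized in log space."""
    lo, hi = max(0, n + K - N), min(n, K)
    ks = np.arange(lo, hi + 1)
    logp = _log_comb(K, ks) + _log_comb(N - K, n - ks) - _log_comb(N, n)
    return ks, np.exp(logp)


def fisher_exact(table: ContingencyTable2x2) -> FisherResult:
    """Fisher's exact test for a 2x2 table.

    The one-sided p is the upper tail P(X >= a); the odds ratio is ad/bc
    (infinite when bc = 0 and ad > 0, nan for the 0/0 case).
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*np.asarray(table, dtype=np.int64).ravel())
    a, b, c, d = table.a, table.b, table.c, table.d
    N, K, n = table.total, a + b, a + c
    ks, pmf = _support_pmf(N, K, n)
    p_obs = pmf[a - ks[0]]
    p_two = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    p_greater = float(pmf[ks >= a].sum())
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(
        p_two_sided=min(1.0, p_two),
        p_one_sided_greater=min(1.0, p_greater),
        odds_ratio=odds,
        table=table,
    )
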