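"""Shared exact statistics.

Two-tailed Fisher exact tests for 2x2 contingency tables, exact binomial and
Poisson tail probabilities, and the continuity-corrected Z-score used by the
motif-enrichment analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _st

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_two_tailed",
    "binomial_upper_tail",
    "binomial_lower_tail",
    "poisson_upper_tail",
    "z_score",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2x2 table of nonnegative counts; rows are groups, columns categories."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be nonnegative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("all-zero contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_two_tailed(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    method: str = "point",
) -> float:
    """Two-tailed Fisher exact p-value for a 2x2 table.

    ``method="point"`` (default) sums the hypergeometric point probabilities of
    every table with the same margins whose probability does not exceed that of
    the observed table (the classic "minimum-likelihood" two-sided test).
    ``method="doubling"`` doubles the smaller one-sided tail, clamped to 1.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    t = [[table.a, table.b], [table.c, table.d]]
    if method == "point":
        return float(min(1.0, _st.fisher_exact(t, alternative="two-sided")[1]))
    if method == "doubling":
        lo = _st.fisher_exact(t, alternative="less")[1]
        hi = _st.fisher_exact(t, alternative="greater")[1]
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError(f"unknown method {method!r}")


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if k == 0:
        return 1.0
    return float(_st.binom.sf(k - 1, n, p))


def binomial_lower_tail(k: int, n: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p).  k < 0 gives 0."""
    if k < 0:
        return 0.0
    return float(_st.binom.cdf(k, n, p))


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam); the small-p limit of the binomial tail."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if k <= 0:
        return 1.0
    return float(_st.poisson.sf(k - 1, lam))


def z_score(observed: float, expected: float, sd: float, continuity: float = 0.5) -> float:
    """Continuity-corrected standardized excess (observed - expected) / sd.

    The correction shrinks the excess toward zero by ``continuity``; when the
    absolute excess does not exceed the correction the score is exactly 0.
    """
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    diff = observed - expected
    if abs(diff) <= continuity:
        return 0.0
    return (diff - math.copysign(continuity, diff)) / sd
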