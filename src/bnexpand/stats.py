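"""Enrichment and group-comparison statistics.

Hypergeometric enrichment asks whether a drawn gene list (e.g. the top 5% of
a ranking) contains more members of an annotation category than expected by
chance: upper-tail p = P(X >= overlap) for X ~ Hypergeom(universe_size,
category_size, draw_size). The >= convention (not >) is used because the
question is "at least this enriched"; exact log-space combinatorics, no
normal approximation.

The one-sided unequal-variance (Welch) t-test compares two groups where the
alternative is mean(group_hi) > mean(group_lo); used here to ask whether
genes found only by single-gene expansion carry more dependences on core
genes than genes also found by co-expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy import stats as sps

from .bde_scoring import AdditionScoreResult
from .errors import DataError

__all__ = [
    "EnrichmentResult",
    "WelchResult",
    "hypergeom_enrichment",
    "welch_t_one_sided",
    "dependence_count_comparison",
]


@dataclass
class EnrichmentResult:
    overlap: int
    draw_size: int
    category_size: int
    universe_size: int
    p_value: float


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def _log_binom(n: float, k: np.ndarray | float) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_enrichment(
    overlap: int,
    draw_size: int,
    category_size: int,
    universe_size: int,
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric enrichment p-value, P(X >= overlap)."""
    for name, v in (("overlap", overlap), ("draw_size", draw_size),
                    ("category_size", category_size), ("universe_size", universe_size)):
        if v < 0:
            raise DataError(f"{name} must be non-negative, got {v}")
    if category_size > universe_size or draw_size > universe_size:
        raise DataError("category_size and draw_size cannot exceed universe_size")
    k_max = min(draw_size, category_size)
    k_min = max(0, draw_size + category_size - universe_size)
    if overlap > k_max:
        raise DataError(f"overlap {overlap} exceeds min(draw, category) = {k_max}")
    if overlap < k_min:
        raise DataError(f"overlap {overlap} below the minimum achievable {k_min}")
    ks = np.arange(max(overlap, k_min), k_max + 1)
    log_pmf = (
        _log_binom(category_size, ks)
        + _log_binom(universe_size - category_size, draw_size - ks)
        - _log_binom(universe_size, draw_size)
    )
    p = float(np.exp(logsumexp(log_pmf)))
    return EnrichmentResult(overlap, draw_size, category_size, universe_size,
                            min(p, 1.0))


def welch_t_one_sided(
    group_hi: Sequence[float],
    group_lo: Sequence[float],
) -> WelchResult:
    """Welch t statistic, Welch-Satterthwaite df and one-sided p for the
    alternative mean(group_hi) > mean(group_lo)."""
    hi = np.asarray(group_hi, dtype=float)
    lo = np.asarray(group_lo, dtype=float)
    if hi.size < 2 or lo.size < 2:
        raise DataError("each group needs at least 2 values")
    if np.var(hi, ddof=1) == 0 and np.var(lo, ddof=1) == 0:
        raise DataError("both groups have zero variance; t undefined")
    res = sps.ttest_ind(hi, lo, equal_var=False, alternative="greater")
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def dependence_count_comparison(
    bayes_only: Sequence[AdditionScoreResult],
    both: Sequence[AdditionScoreResult],
) -> WelchResult:
    """Are dependence counts higher for genes found only by expansion than
    for genes found by both methods? One-sided Welch test."""
    if len(bayes_only) < 2 or len(both) < 2:
        raise DataError("each group needs at least 2 genes")
    return welch_t_one_sided(
        [r.n_dependences for r in bayes_only],
        [r.n_dependences for r in both],
    )
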