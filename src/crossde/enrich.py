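"""Hypergeometric over-representation of gene categories.

For a query of n genes drawn from a background universe of N genes, of
which K belong to a category, the overlap k is tested against the
upper-tail hypergeometric probability P(X >= k), and summarized by the
fold enrichment (k/n)/(K/N). No multiplicity adjustment is applied by
default (the convention for a small number of custom categories tested at
a fixed alpha); Benjamini-Hochberg across categories is available by flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .diffexpr import adjust_bh
from .errors import ValidationError
from .io import GeneSetCategory

__all__ = ["EnrichmentResult", "hypergeom_upper", "fold_enrichment", "enrich"]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Over-representation outcome for one category."""

    category: str
    N: int  # background size
    K: int  # category members in background
    n: int  # query size (in background)
    k: int  # overlap
    fold_enrichment: float
    p: float
    overlap_genes: tuple[str, ...]
    p_adj: float | None = None


def _check_bounds(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N):
        raise ValidationError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValidationError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"require 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail p-value P(X >= k), X ~ Hypergeometric(N, K, n).

    k = 0 is the certain event (p = 1). Computed from the survival
    function of the hypergeometric distribution, which accumulates the
    tail in a numerically stable way.
    """
    _check_bounds(N, K, n, k)
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, math.ulp(0.0)), 1.0)


def fold_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Observed/expected overlap ratio: (k/n)/(K/N)."""
    _check_bounds(N, K, n, k)
    if K == 0:
        raise ValidationError("category has no members in the background (K = 0)")
    if n == 0:
        raise ValidationError("query is empty within the background (n = 0)")
    return (k / n) / (K / N)


def enrich(
    query: set[str],
    categories: list[GeneSetCategory],
    background: set[str],
    adjust: str = "none",
) -> list[EnrichmentResult]:
    """Test each category for over-representation in the query.

    Query genes outside the background are dropped with a logged warning;
    category membership is likewise restricted to the background before
    counting. A category entirely absent from the background yields k = 0,
    p = 1 and fold enrichment 0.
    """
    if adjust not in ("none", "bh"):
        raise ValidationError(f"unknown adjustment '{adjust}'")
    if not background:
        raise ValidationError("background universe is empty")
    dropped = query - background
    if dropped:
        logger.warning(
            "%d query gene(s) outside the background dropped: %s%s",
            len(dropped),
            sorted(dropped)[:5],
            "..." if len(dropped) > 5 else "",
        )
    q = query & background
    N, n = len(background), len(q)

    results: list[EnrichmentResult] = []
    for cat in categories:
        members = cat.member_set & background
        K = len(members)
        overlap = tuple(sorted(members & q))
        k = len(overlap)
        p = hypergeom_upper(N, K, n, k)
        fold = fold_enrichment(N, K, n, k) if (K > 0 and n > 0) else 0.0
        results.append(
            EnrichmentResult(
                category=cat.name, N=N, K=K, n=n, k=k,
                fold_enrichment=fold, p=p, overlap_genes=overlap,
            )
        )
    if adjust == "bh" and results:
        adjusted = adjust_bh([r.p for r in results])
        for r, pa in zip(results, adjusted):
            r.p_adj = float(pa)
    return results
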