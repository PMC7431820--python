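"""Hypergeometric overlap testing for gene/CpG set intersections.

Used for overrepresentation questions such as "do the most heritable CpGs
fall in polycomb-group target (PCGT) genes more often than chance?": draw a
query set of size n from a universe of N elements of which K belong to the
target set, and ask whether the observed overlap k is surprisingly large.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy import stats

__all__ = ["OverlapTest", "hypergeom_overlap", "overlap_from_sets"]


@dataclass(frozen=True)
class OverlapTest:
    """Upper-tail hypergeometric overlap test with fold enrichment.

    ``p_upper`` is P(X >= k) for X ~ Hypergeometric(N, K, n) — the observed
    count is included, the standard overrepresentation convention.
    """

    k: int
    K: int
    n: int
    N: int
    p_upper: float
    fold_enrichment: float
    overlap_fraction: float


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> OverlapTest:
    """Test whether an overlap of ``k`` between a target set of size ``K`` and
    a query set of size ``n`` in a universe of ``N`` is larger than chance.

    Fold enrichment is k / (K n / N) (observed over expected); the overlap
    fraction is k / K, i.e. the share of the target set that is hit.
    """
    if min(k, K, n, N) < 0:
        raise ValueError("counts must be non-negative")
    if K > N or n > N:
        raise ValueError("set sizes cannot exceed the universe size")
    if k > min(K, n):
        raise ValueError("overlap cannot exceed either set size")
    if N == 0 or K == 0 or n == 0:
        raise ValueError("universe and both sets must be nonempty")
    p_upper = float(stats.hypergeom.sf(k - 1, N, K, n))
    expected = K * n / N
    return OverlapTest(
        k=k,
        K=K,
        n=n,
        N=N,
        p_upper=p_upper,
        fold_enrichment=k / expected,
        overlap_fraction=k / K,
    )


def overlap_from_sets(
    query: Iterable, target: Iterable, universe: Iterable
) -> OverlapTest:
    """Overlap test from explicit element sets (restricted to the universe)."""
    universe = set(universe)
    query = set(query) & universe
    target = set(target) & universe
    return hypergeom_overlap(
        k=len(query & target), K=len(target), n=len(query), N=len(universe)
    )
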