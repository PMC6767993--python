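"""Pathway over-representation analysis for a gene list.

Given a query (here: the major hubs), a gene-set collection and a universe,
each pathway is tested for over-representation of query genes under
hypergeometric sampling. Two statistics are offered:

* ``hypergeometric`` — the exact upper tail P(X >= k) for overlap k, query
  size n, pathway size K, universe size N, computed as an exact integer
  tail sum of binomial-coefficient products (no floating-point summation of
  near-cancelling terms);
* ``ease`` — the conservative variant popularized by the DAVID service:
  the same tail evaluated at k - 1 (one overlap gene removed), so
  single-gene overlaps are never significant. This is the default, matching
  common practice for hub-list annotation.

Multiple testing is corrected with Benjamini-Hochberg by default (``none``
reproduces raw-p presentations). P-values are computed for every pathway
with a nonempty universe-intersected gene set; only pathways with overlap
>= 1 are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Iterator, Sequence

from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import PathwayGeneSet, canonical_symbol

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    overlap_count: int
    pathway_size: int
    query_size: int
    universe_size: int
    p_value: float
    p_adjusted: float
    overlap_genes: frozenset[str]


@dataclass
class EnrichmentReport:
    """Sorted results plus the count of query genes outside the universe."""

    results: list[EnrichmentResult]
    query_dropped: int = 0

    def __iter__(self) -> Iterator[EnrichmentResult]:
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, i):
        return self.results[i]


def _validate_params(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) <= N and n <= N and K <= N):
        raise ValidationError(
            f"inconsistent hypergeometric parameters k={k}, n={n}, K={K}, N={N}"
        )


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact.

    The tail is summed in integer arithmetic — sum over i >= k of
    C(K, i) * C(N-K, n-i) — and divided by C(N, n) once at the end.
    """
    _validate_params(k, n, K, N)
    numer = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return numer / comb(N, n)


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """DAVID-style conservative tail: hypergeometric_tail at k - 1."""
    if k < 1:
        raise ValidationError("ease_score requires overlap k >= 1")
    _validate_params(k, n, K, N)
    return hypergeometric_tail(k - 1, n, K, N)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up BH adjustment with monotonicity enforcement, capped at 1."""
    if len(p_values) == 0:
        return []
    return list(multipletests(list(p_values), method="fdr_bh")[1])


def enrich(
    query: set[str],
    gene_sets: Sequence[PathwayGeneSet],
    universe: set[str] | None = None,
    method: str = "ease",
    adjust: str = "benjamini_hochberg",
) -> EnrichmentReport:
    """Over-representation of ``query`` in each pathway of ``gene_sets``.

    ``universe`` defaults to the union of all genes across the collection;
    query genes outside the universe are dropped (counted on the report) and
    gene sets are intersected with the universe before testing.
    """
    if method not in ("hypergeometric", "ease"):
        raise ValidationError(f"unknown method {method!r}")
    if adjust not in ("benjamini_hochberg", "none"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    universe_c = (
        {canonical_symbol(g) for g in universe}
        if universe is not None
        else set().union(*(gs.genes for gs in gene_sets)) if gene_sets else set()
    )
    if not universe_c:
        raise ValidationError("empty universe")
    query_c = {canonical_symbol(g) for g in query}
    dropped = len(query_c - universe_c)
    if dropped:
        log.info("enrich: dropped %d query genes outside the universe", dropped)
    query_c &= universe_c

    N = len(universe_c)
    n = len(query_c)
    stat = ease_score if method == "ease" else hypergeometric_tail

    tested: list[tuple[PathwayGeneSet, frozenset[str], float]] = []
    for gs in gene_sets:
        genes = frozenset(gs.genes & universe_c)
        if not genes:
            continue
        overlap = genes & query_c
        p = stat(len(overlap), n, len(genes), N) if overlap else 1.0
        tested.append((gs, overlap, p))

    raw = [p for _, _, p in tested]
    adjusted = benjamini_hochberg(raw) if adjust == "benjamini_hochberg" else raw

    results = [
        EnrichmentResult(
            pathway_id=gs.pathway_id,
            pathway_name=gs.pathway_name,
            overlap_count=len(overlap),
            pathway_size=len(gs.genes & universe_c),
            query_size=n,
            universe_size=N,
            p_value=p,
            p_adjusted=p_adj,
            overlap_genes=overlap,
        )
        for (gs, overlap, p), p_adj in zip(tested, adjusted)
        if overlap
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return EnrichmentReport(results, dropped)
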