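"""Hypergeometric over-representation with Benjamini–Hochberg FDR control.

Given a query set of m target ids drawn from a universe of size M, the
enrichment p-value of a gene set of size K with k0 query hits is the
upper-tail hypergeometric probability of drawing k0 or more set members
in m draws without replacement:

    p = sum_{k = k0}^{min(K, m)} C(K, k) C(M-K, m-k) / C(M, m)

The universe is the collection's explicit target universe (a mandatory
input — what background the original analyses used is rarely stated, so
it is never guessed here). Raw p-values are adjusted across all sets of
the collection by the standard BH step-up. Two reporting conventions are
supported: full tables ranked by ascending p, and a filtered view at raw
p < alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_data import CATEGORIES, DrugCatalog, GeneSetCollection, InteractionSet

logger = logging.getLogger("autoqsp")

DEFAULT_ALPHA = 0.05


def hypergeom_upper_tail(k0: int, K: int, m: int, M_universe: int) -> float:
    """P(X >= k0) for X ~ Hypergeom(M_universe, K, m).

    Returns 1 when k0 <= 0 (the full support) and 0 when k0 exceeds
    min(K, m) (an impossible event). Delegates the tail sum to a
    numerically stable survival-function evaluation.
    """
    if not (0 <= K <= M_universe):
        raise ValueError(f"need 0 <= K <= M_universe, got K={K}, M={M_universe}")
    if not (0 <= m <= M_universe):
        raise ValueError(f"need 0 <= m <= M_universe, got m={m}, M={M_universe}")
    if k0 < 0:
        raise ValueError(f"k0 must be >= 0, got {k0}")
    if k0 == 0:
        return 1.0
    if k0 > min(K, m):
        return 0.0
    return float(hypergeom.sf(k0 - 1, M_universe, K, m))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, in input order.

    For ascending-sorted p_(1) <= ... <= p_(n):
    p*_(i) = min_{k >= i} min(p_(k) * n / k, 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    # guard against 1-ulp rounding of p*(n/k) at k = n pushing p_adj below p
    adjusted = np.maximum(adjusted, p[order])
    out = np.empty(n)
    out[order] = adjusted
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """Counts and p-values for one gene set against one query."""

    set_id: str
    k0: int  # query hits inside the set
    K: int  # set size within the universe
    m: int  # query size
    M_universe: int
    p: float
    p_adj: float
    rank: int

    def __post_init__(self) -> None:
        if not (0 <= self.k0 <= min(self.K, self.m)):
            raise ValueError("k0 outside [0, min(K, m)]")
        if not (0.0 < self.p <= 1.0 and self.p <= self.p_adj <= 1.0):
            raise ValueError("p/p_adj outside expected ranges")


def enrich(query: Iterable[str], collection: GeneSetCollection) -> list[EnrichmentResult]:
    """One result per set, BH-adjusted across the whole collection.

    Query ids outside the universe are dropped with a logged count;
    results are sorted by ascending p, ties broken by set id.
    """
    requested = set(query)
    inside = requested & collection.universe
    dropped = len(requested) - len(inside)
    if dropped:
        logger.info("enrich: dropped %d query ids outside the universe", dropped)
    if not inside:
        raise ValueError("query is empty after intersecting with the universe")
    m = len(inside)
    M = len(collection.universe)
    set_ids = sorted(collection.sets)
    raw = []
    counts = []
    for set_id in set_ids:
        members = collection.members(set_id)
        k0 = len(inside & members)
        counts.append((set_id, k0, len(members)))
        raw.append(hypergeom_upper_tail(k0, len(members), m, M))
    adjusted = bh_adjust(raw)
    order = sorted(range(len(set_ids)), key=lambda i: (raw[i], set_ids[i]))
    results = []
    for rank, i in enumerate(order, start=1):
        set_id, k0, K = counts[i]
        results.append(
            EnrichmentResult(set_id, k0, K, m, M, raw[i], float(adjusted[i]), rank)
        )
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_id, r.k0, r.K, r.m, r.M_universe, r.p, r.p_adj, r.rank)
            for r in results
        ],
        columns=["set_id", "k0", "K", "m", "M", "p", "p_adj", "rank"],
    )


def significant(
    results: Sequence[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
    adjusted: bool = False,
) -> list[EnrichmentResult]:
    """Filtered view at p < alpha (raw by default, matching the reporting
    convention of ranked enrichment tables; set adjusted=True for FDR)."""
    key = (lambda r: r.p_adj) if adjusted else (lambda r: r.p)
    return [r for r in results if key(r) < alpha]


def category_target_sets(
    catalog: DrugCatalog,
    interactions: InteractionSet,
    include_predicted: bool = False,
) -> dict[str, set[str]]:
    """Union of targets per modulator category (known edges; plus
    predicted edges when include_predicted is set)."""
    edges = interactions.edges
    if not include_predicted:
        edges = edges[edges["provenance"] == "known"]
    out: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    for drug, target in zip(edges["drug_id"], edges["target_id"]):
        out[catalog.category_of(drug)].add(target)
    return out


def enrich_by_category(
    catalog: DrugCatalog,
    interactions: InteractionSet,
    collection: GeneSetCollection,
    include_predicted: bool = False,
) -> dict[str, list[EnrichmentResult]]:
    """Enrichment per modulator category plus the pooled query.

    The pooled query is the union of the three category queries. A
    category with no targets yields an empty result list (with a warning)
    rather than an error.
    """
    queries = category_target_sets(catalog, interactions, include_predicted)
    results: dict[str, list[EnrichmentResult]] = {}
    pooled: set[str] = set()
    for category in CATEGORIES:
        query = queries[category]
        pooled |= query
        if not (query & collection.universe):
            logger.warning("enrich_by_category: category %r has no targets", category)
            results[category] = []
            continue
        results[category] = enrich(query, collection)
    if not (pooled & collection.universe):
        raise ValueError("no category has any target inside the universe")
    results["pooled"] = enrich(pooled, collection)
    return results
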