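"""Hypergeometric over-representation of hub target genes in gene sets.

For each hub, the query is the de-duplicated union of mRNAs inversely
correlated with the hub's miRNAs. Each gene set is tested for overlap with
the query by the one-sided (upper-tail) hypergeometric test within an
explicit universe, and Benjamini-Hochberg adjusted q-values are computed
across all sets in the collection. The universe defaults to the genes
present in both the expression data and the collection — web enrichment
services hide their universe, so here it is an explicit, logged parameter.

Reporting truncation (top 10 sets with q < 0.05) is applied only in the
report view; the full result table is always retained.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import CorrelationEdgeSet
from .io import GeneSetCollection, ValidationError
from .network import Hub

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hub_target_genes",
    "hypergeom_overlap_p",
    "bh_fdr",
    "enrich",
    "top_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of one gene set with one query list.

    ``overlap_k`` of the ``query_size_n`` query genes fall in the set of
    ``set_size_K`` universe genes, out of a universe of ``universe_N``.
    """

    set_name: str
    overlap_k: int
    set_size_K: int
    query_size_n: int
    universe_N: int
    p: float
    q: float


def hub_target_genes(hub: Hub, edge_set: CorrelationEdgeSet) -> list[str]:
    """De-duplicated union of mRNA partners of the hub's miRNAs.

    Order follows first appearance in the edge list, so results are
    deterministic for a given edge set.
    """
    known = set(edge_set.mirna_ids)
    unknown = sorted(set(hub.member_mirnas) - known)
    if unknown:
        raise ValidationError(f"hub miRNAs absent from edge set: {unknown}")
    members = set(hub.member_mirnas)
    genes: list[str] = []
    seen: set[str] = set()
    for e in edge_set.edges:
        if e.mirna_id in members and e.mrna_id not in seen:
            genes.append(e.mrna_id)
            seen.add(e.mrna_id)
    return genes


def hypergeom_overlap_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail overlap probability P(X >= k), X ~ Hypergeometric(N, K, n).

    ``k`` observed overlap, ``n`` query size, ``K`` set size, ``N`` universe
    size. Computed through the survival function in log-space internally,
    so tiny tail probabilities do not underflow to zero prematurely.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValidationError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("bh_fdr expects a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    np.clip(q_sorted, 0.0, 1.0, out=q_sorted)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def enrich(
    genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Over-representation of ``genes`` in every set of ``collection``.

    Every set is intersected with the universe before testing, and the query
    must be contained in the universe. Results are ranked by ascending p
    (ties broken by set name). One result per set, q over all sets.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty universe")
    query = [g for g in dict.fromkeys(genes)]
    outside = sorted(set(query) - universe_set)
    if outside:
        raise ValidationError(f"query genes outside the universe: {outside[:5]}")
    n = len(query)
    N = len(universe_set)
    query_set = set(query)
    names, ks, Ks, ps = [], [], [], []
    for name, members in collection.sets.items():
        in_universe = universe_set.intersection(members)
        K = len(in_universe)
        k = len(query_set & in_universe)
        names.append(name)
        ks.append(k)
        Ks.append(K)
        ps.append(hypergeom_overlap_p(k, n, K, N) if K else 1.0)
    qs = bh_fdr(ps)
    results = [
        EnrichmentResult(
            set_name=name,
            overlap_k=k,
            set_size_K=K,
            query_size_n=n,
            universe_N=N,
            p=p,
            q=float(q),
        )
        for name, k, K, p, q in zip(names, ks, Ks, ps, qs)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    log.info(
        "enrich: query of %d genes vs %d sets in universe of %d", n, len(results), N
    )
    return results


def top_table(
    results: Sequence[EnrichmentResult], q_cutoff: float = 0.05, top_k: int = 10
) -> pd.DataFrame:
    """Report view: at most the ``top_k`` lowest-p sets with q < ``q_cutoff``."""
    rows = [r for r in results if r.q < q_cutoff][:top_k]
    return results_frame(rows)


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_name, r.overlap_k, r.set_size_K, r.query_size_n, r.universe_N, r.p, r.q)
            for r in results
        ],
        columns=["set_name", "k", "K", "n", "N", "p", "q"],
    )
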