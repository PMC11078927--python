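"""Overrepresentation analysis of gene sets by the hypergeometric test.

Given a DEG list, a GMT collection and a universe (by default the genes
the DE stage actually tested), each term is scored with the exact
hypergeometric upper-tail probability of observing at least the seen
overlap, followed by Benjamini-Hochberg adjustment across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import GeneSetCollection

__all__ = ["EnrichmentResult", "overrepresentation_test", "results_to_frame"]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap DEGs-in-term
    n: int  # DEG-list size within universe
    K: int  # term size within universe
    N: int  # universe size
    p: float
    padj: float


def overrepresentation_test(
    degs: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    min_size: int = 5,
    max_size: int = 500,
) -> list[EnrichmentResult]:
    """Exact hypergeometric upper-tail test per term, BH across terms.

    DEGs are intersected with the universe; terms are intersected with
    the universe and then filtered to min_size <= K <= max_size. Results
    are sorted by p ascending (ties by term id). An empty DEG set yields
    an empty list; an empty universe is an error.
    """
    if not universe:
        raise ValueError("enrichment universe is empty")
    degs = set(degs) & set(universe)
    if not degs:
        return []
    N = len(universe)
    n = len(degs)
    tested = []
    for term_id in sets:
        gs = sets[term_id]
        term_genes = gs.genes & universe
        K = len(term_genes)
        if K < min_size or K > max_size:
            continue
        k = len(term_genes & degs)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        tested.append((term_id, gs.term_name, k, K, min(p, 1.0)))
    if not tested:
        return []
    padj = bh_adjust([t[4] for t in tested])
    results = [
        EnrichmentResult(term_id, name, k, n, K, N, p, float(q))
        for (term_id, name, k, K, p), q in zip(tested, padj)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "p": r.p,
            "padj": r.padj,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p", "padj"]
    )
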