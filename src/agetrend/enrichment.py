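"""Hypergeometric over-representation analysis with BH-FDR.

A query gene set (e.g. the screen's significant genes in one tissue, or
one MCL cluster) is tested against each annotation term for
over-representation: with a universe of N genes of which K carry the
term and a query of n genes of which k carry it, the one-sided p-value
is the hypergeometric upper tail P[X >= k] (equivalently one-sided
Fisher's exact).  Benjamini-Hochberg q-values are computed over exactly
the set of tested terms.  Two significance flags are carried per result,
at FDR 0.01 (tissue-level convention) and 0.05 (network-level
convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AnnotationCollection

__all__ = ["EnrichmentResult", "hypergeom_upper", "bh_fdr", "enrich", "enrichment_to_frame"]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    overlap_genes: frozenset[str]
    significant_fdr01: bool = False
    significant_fdr05: bool = False


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts term genes in a size-n draw without replacement from a
    universe of N genes containing K term genes.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"infeasible overlap k={k} for K={K}, n={n}")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"infeasible counts K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(ps, method="fdr_bh")[1])


def enrich(
    query: Iterable[str],
    annotations: AnnotationCollection,
    universe_mode: Literal["collection_union", "explicit"] = "collection_union",
    universe: Iterable[str] | None = None,
    include_zero_overlap: bool = False,
) -> list[EnrichmentResult]:
    """Over-representation of a query set against every annotation term.

    The universe defaults to the union of all genes in the collection;
    an explicit universe restricts both the query and every term to it.
    Terms with zero query overlap are excluded from testing by default
    (this changes the BH family size, hence the switch).  Results are
    sorted by q, then p, then term id.
    """
    if universe_mode == "explicit":
        if universe is None:
            raise ValueError("explicit universe mode requires a universe")
        uni = set(universe)
    else:
        uni = annotations.universe
    query_in = set(query) & uni
    if not query_in:
        raise ValueError("query is empty after intersection with the universe")
    N = len(uni)
    n = len(query_in)

    tested: list[EnrichmentResult] = []
    for tid, (name, genes) in sorted(annotations.items()):
        genes_in = genes & uni
        K = len(genes_in)
        if K == 0:
            continue
        overlap = query_in & genes_in
        k = len(overlap)
        if k == 0 and not include_zero_overlap:
            continue
        p = hypergeom_upper(k, K, n, N)
        tested.append(EnrichmentResult(tid, name, k, K, n, N, p, q=1.0,
                                       overlap_genes=frozenset(overlap)))
    if not tested:
        return []
    qs = bh_fdr([r.p for r in tested])
    for r, q in zip(tested, qs):
        r.q = float(q)
        r.significant_fdr01 = bool(q < 0.01)
        r.significant_fdr05 = bool(q < 0.05)
    tested.sort(key=lambda r: (r.q, r.p, r.term_id))
    return tested


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p": r.p,
            "q": r.q,
            "significant_fdr01": r.significant_fdr01,
            "significant_fdr05": r.significant_fdr05,
            "overlap_genes": ";".join(sorted(r.overlap_genes)),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
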