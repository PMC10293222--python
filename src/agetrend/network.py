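"""Interaction subnetwork induction, summary statistics and a
size-matched permutation null for connectivity.

Given a scored edge list (STRING-style confidences in [0, 1]) and a set
of screen-significant genes, the induced network keeps edges whose two
endpoints are both in the set, whose score clears the confidence cutoff
(default 0.400, inclusive, matching the medium-confidence convention)
and whose evidence channel matches (default: physical; edges without
channel information pass).  Connectivity against chance is assessed by
resampling same-sized gene sets uniformly from the edge list's node
universe and comparing induced edge counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import ScoredEdgeList, canonical_edge

__all__ = [
    "InteractionNetwork",
    "NetworkStats",
    "induce_network",
    "network_stats",
    "connectivity_pvalue",
]

DEFAULT_MIN_SCORE = 0.400


@dataclass
class InteractionNetwork:
    """Undirected scored gene graph with provenance of the filter applied."""

    graph: nx.Graph
    min_score: float
    channel: str | None
    strict: bool = False

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        return {
            canonical_edge(a, b): d["score"] for a, b, d in self.graph.edges(data=True)
        }

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_edge_frame(self) -> pd.DataFrame:
        rows = sorted((a, b, s) for (a, b), s in self.edges.items())
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])

    def to_node_frame(self) -> pd.DataFrame:
        rows = sorted((n, self.graph.degree(n)) for n in self.graph.nodes)
        return pd.DataFrame(rows, columns=["gene", "degree"])


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    mean_degree: float
    degree_sequence: list[int]
    n_isolated: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_nodes": self.n_nodes,
                    "n_edges": self.n_edges,
                    "mean_degree": self.mean_degree,
                    "n_isolated": self.n_isolated,
                }
            ]
        )


def induce_network(
    edges: ScoredEdgeList,
    genes: Iterable[str],
    min_score: float = DEFAULT_MIN_SCORE,
    channel: str | None = "physical",
    strict: bool = False,
    keep_isolated: bool = True,
) -> InteractionNetwork:
    """Subnetwork over ``genes`` at the given confidence cutoff.

    ``strict=False`` retains edges with score >= min_score (STRING
    medium-confidence convention); ``strict=True`` requires >.  Genes
    without any retained edge stay as degree-0 nodes unless
    ``keep_isolated`` is false.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    genes = set(genes)
    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(sorted(genes))
    for a, b, score, chan in edges.filtered(min_score, strict=strict, channel=channel):
        if a in genes and b in genes:
            g.add_edge(a, b, score=score)
    return InteractionNetwork(g, min_score, channel, strict)


def network_stats(net: InteractionNetwork, include_isolated: bool = True) -> NetworkStats:
    """Node/edge counts, mean degree and degree sequence.

    With ``include_isolated=False`` degree-0 nodes are excluded from the
    node count before the mean degree (the two counting conventions for
    a network with isolated members).
    """
    degrees = dict(net.graph.degree())
    n_isolated = sum(1 for d in degrees.values() if d == 0)
    if not include_isolated:
        degrees = {n: d for n, d in degrees.items() if d > 0}
    n_nodes = len(degrees)
    n_edges = net.n_edges
    mean_degree = (2.0 * n_edges / n_nodes) if n_nodes else math.nan
    return NetworkStats(
        n_nodes=n_nodes,
        n_edges=n_edges,
        mean_degree=mean_degree,
        degree_sequence=sorted(degrees.values()),
        n_isolated=n_isolated,
    )


def induced_edge_count(edges: ScoredEdgeList, genes: set[str], min_score: float,
                       strict: bool = False, channel: str | None = None) -> int:
    """Number of retained edges with both endpoints in ``genes``."""
    count = 0
    for a, b, score, chan in edges.filtered(min_score, strict=strict, channel=channel):
        if a in genes and b in genes:
            count += 1
    return count


def connectivity_pvalue(
    edges: ScoredEdgeList,
    genes: Iterable[str],
    min_score: float = DEFAULT_MIN_SCORE,
    n_perm: int = 1000,
    seed: int = 0,
    strict: bool = False,
    channel: str | None = None,
) -> tuple[int, float]:
    """Permutation p-value for the induced edge count of a gene set.

    The null resamples uniform gene sets of the same size from the edge
    list's node universe; p = (1 + #{resamples with edge count >=
    observed}) / (1 + n_perm), the add-one estimator, so p is always in
    (0, 1].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = set(genes)
    universe = sorted(edges.nodes)
    if len(genes) > len(universe):
        raise ValueError(
            f"gene set ({len(genes)}) larger than edge-list universe ({len(universe)})"
        )
    filt = edges.filtered(min_score, strict=strict, channel=channel).to_frame()
    node_index = {n: i for i, n in enumerate(universe)}
    u = filt["protein_a"].map(node_index).to_numpy()
    v = filt["protein_b"].map(node_index).to_numpy()

    member = np.zeros(len(universe), dtype=bool)
    member[[node_index[g] for g in genes if g in node_index]] = True
    observed = int(np.count_nonzero(member[u] & member[v]))

    rng = np.random.default_rng(seed)
    k = len(genes)
    at_least = 0
    for _ in range(n_perm):
        pick = rng.choice(len(universe), size=k, replace=False)
        mask = np.zeros(len(universe), dtype=bool)
        mask[pick] = True
        if int(np.count_nonzero(mask[u] & mask[v])) >= observed:
            at_least += 1
    p = (1 + at_least) / (1 + n_perm)
    return observed, p
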