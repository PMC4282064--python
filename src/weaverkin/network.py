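"""Colony association networks from shared chamber use.

An edge joins two birds that used at least one common nest chamber within
the same observation series ("gambit of the group" applied to chamber
co-use); the default edge weight is the number of distinct shared chambers.
Centrality (normalised weighted degree and betweenness) and Girvan–Newman
community partitions with weighted modularity follow.

Shortest paths treat edge length as the reciprocal of association weight:
strongly associated birds are "close".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import ObservationLog

__all__ = [
    "AssociationNetwork",
    "PartitionResult",
    "build_network",
    "centrality",
    "girvan_newman",
    "modularity",
]

WEIGHT_DIALECTS = ("shared_chambers", "co_entries", "simple_ratio")


@dataclass
class AssociationNetwork:
    """Weighted undirected network of one colony's chamber co-use."""

    colony_id: str
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def weight_matrix(self, order=None) -> np.ndarray:
        order = list(self.graph.nodes) if order is None else list(order)
        return nx.to_numpy_array(self.graph, nodelist=order, weight="weight")


def build_network(
    obs: ObservationLog,
    colony_id: str,
    series_id: str | None = None,
    dialect: str = "shared_chambers",
    node_attrs: dict | None = None,
) -> AssociationNetwork:
    """Build one colony's association network from its observation entries.

    Weight dialects:

    ``shared_chambers`` (default)
        number of distinct chambers both birds entered;
    ``co_entries``
        sum over shared chambers of min(entries by each bird);
    ``simple_ratio``
        shared chambers / chambers used by either bird (in (0, 1]).

    Birds observed but sharing no chamber stay in the network as isolated
    nodes.  All observed birds at the colony are included — cross-colony
    edges never arise because networks are built per colony.
    """
    if dialect not in WEIGHT_DIALECTS:
        raise ValueError(f"unknown weight dialect {dialect!r}; choose from {WEIGHT_DIALECTS}")
    entries = obs.for_colony(colony_id, series_id).entries
    g = nx.Graph()
    if entries.empty:
        warnings.warn(f"colony {colony_id!r}: no observations; empty network", stacklevel=2)
        return AssociationNetwork(colony_id, g)
    counts = entries.groupby(["bird_id", "chamber_id"]).size()
    chambers_of: dict[str, dict[str, int]] = {}
    for (bird, chamber), k in counts.items():
        chambers_of.setdefault(bird, {})[chamber] = int(k)
    birds = sorted(chambers_of)
    g.add_nodes_from(birds)
    for i, a in enumerate(birds):
        ca = chambers_of[a]
        for b in birds[i + 1:]:
            cb = chambers_of[b]
            shared = ca.keys() & cb.keys()
            if not shared:
                continue
            if dialect == "shared_chambers":
                w = float(len(shared))
            elif dialect == "co_entries":
                w = float(sum(min(ca[c], cb[c]) for c in shared))
            else:  # simple_ratio
                w = len(shared) / len(ca.keys() | cb.keys())
            g.add_edge(a, b, weight=w, length=1.0 / w)
    if node_attrs:
        for bird in birds:
            g.nodes[bird].update(node_attrs.get(bird, {}))
    return AssociationNetwork(colony_id, g)


def centrality(net: AssociationNetwork) -> pd.DataFrame:
    """Normalised weighted degree k and betweenness B per node.

    k is node strength (sum of incident weights) divided by (n-1) * w_max,
    so k = 1 for a node tied to everyone at the maximum observed weight; B
    is weighted shortest-path betweenness (edge length 1/weight) divided by
    (n-1)(n-2)/2.  Both are invariant to a uniform rescaling of weights and
    comparable across colonies of different size.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("centrality needs at least 2 nodes")
    w_max = max((w for _, _, w in g.edges(data="weight")), default=0.0)
    if w_max > 0:
        k = {v: g.degree(v, weight="weight") / ((n - 1) * w_max) for v in g}
    else:
        k = {v: 0.0 for v in g}
    if n < 3 or g.number_of_edges() == 0:
        b = {v: 0.0 for v in g}
    else:
        b = nx.betweenness_centrality(g, weight="length", normalized=True)
    return pd.DataFrame({"k": pd.Series(k), "B": pd.Series(b)}).loc[list(g.nodes)]


def modularity(net: AssociationNetwork, partition) -> float:
    """Weighted Newman–Girvan modularity Q of a node partition.

    Q = sum_c (e_cc - a_c^2) with e the fraction of total edge weight inside
    community c and a_c the fraction of edge-weight endpoints in c.  The
    all-in-one partition scores exactly 0.
    """
    g = net.graph
    total = g.size(weight="weight")
    if total <= 0:
        raise ValueError("modularity undefined: network has zero total edge weight")
    communities = [set(c) for c in partition]
    covered = set().union(*communities) if communities else set()
    if covered != set(g.nodes):
        raise ValueError("partition does not cover all nodes exactly")
    return float(nx.community.modularity(g, communities, weight="weight"))


@dataclass
class PartitionResult:
    """Profile of nested Girvan–Newman partitions and the modularity optimum."""

    partitions: list[list[set]]  # recorded partitions, coarse to fine
    q_values: list[float]
    best_index: int

    @property
    def best_partition(self) -> list[set]:
        return self.partitions[self.best_index]

    @property
    def best_q(self) -> float:
        return self.q_values[self.best_index]

    @property
    def n_partitions(self) -> int:
        return len(self.best_partition)

    def membership(self) -> dict[str, int]:
        return {v: i for i, part in enumerate(self.best_partition) for v in part}


def girvan_newman(net: AssociationNetwork) -> PartitionResult:
    """Girvan–Newman community detection with weighted edge betweenness.

    Edges are removed one at a time in decreasing order of weighted edge
    betweenness (edge length 1/weight, recomputed after every removal); a
    partition is recorded each time the number of connected components
    grows.  Weighted modularity Q is evaluated on every recorded partition
    — including the initial one, so the trivial single-community split
    (Q = 0) for a connected graph is always a candidate — and the partition
    maximising Q is selected, ties resolved toward fewer communities.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return PartitionResult([[set()]], [0.0], 0)
    if g.number_of_edges() == 0:
        parts = [{v} for v in g.nodes]
        return PartitionResult([parts], [0.0], 0)
    work = g.copy()
    partitions = [[set(c) for c in nx.connected_components(work)]]
    n_comp = len(partitions[0])
    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work, weight="length")
        edge = max(sorted(eb), key=eb.get)
        work.remove_edge(*edge)
        comps = [set(c) for c in nx.connected_components(work)]
        if len(comps) > n_comp:
            n_comp = len(comps)
            partitions.append(comps)
    q_values = [modularity(net, p) for p in partitions]
    best = int(np.argmax(q_values))  # argmax takes the first (coarsest) on ties
    return PartitionResult(partitions, q_values, best)
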