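"""Divisive community detection by iterative edge-betweenness removal.

The algorithm repeatedly removes the edge with the highest betweenness
(number of shortest paths between all vertex pairs running along the edge,
with multiple shortest paths between a pair splitting the unit of weight
equally) and recomputes betweenness on the depleted graph, until no edges
remain. Each time the number of connected components increases, the
component partition is recorded together with its modularity

    Q = Tr(e) - sum_i a_i^2

where e_ij is the fraction of the *original* network's edges linking
community i to community j (an inter-community edge contributes 1/2 to
e_ij and 1/2 to e_ji) and a_i are the row sums of e. The partition with
the peak Q is the optimal cut of the dendrogram.

The graph is treated as unweighted throughout; the exact recompute loop is
O(m^2 n). Ties on the maximal betweenness are broken uniformly at random
under a caller-supplied seed.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .network import InteractionNetwork

Edge = tuple[Hashable, Hashable]

#: relative tolerance for detecting ties between floating betweenness values
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class Partition:
    """Assignment of every vertex to one of k dense community ids."""

    assignment: Mapping[Hashable, int]
    k: int

    def __post_init__(self) -> None:
        ids = set(self.assignment.values())
        if ids and (min(ids) != 0 or max(ids) != self.k - 1 or len(ids) != self.k):
            raise ValueError("community ids must be dense 0..k-1")

    @classmethod
    def from_components(cls, graph: nx.Graph) -> "Partition":
        comps = sorted(
            (sorted(c, key=str) for c in nx.connected_components(graph)),
            key=lambda c: str(c[0]),
        )
        assignment = {v: i for i, comp in enumerate(comps) for v in comp}
        return cls(assignment=assignment, k=len(comps))

    @classmethod
    def from_labels(cls, labels: Mapping[Hashable, Hashable]) -> "Partition":
        """Build a partition from arbitrary labels, densifying the ids."""
        uniq = sorted({str(l) for l in labels.values()})
        lut = {l: i for i, l in enumerate(uniq)}
        return cls(assignment={v: lut[str(l)] for v, l in labels.items()}, k=len(uniq))

    def communities(self) -> list[list[Hashable]]:
        out: list[list[Hashable]] = [[] for _ in range(self.k)]
        for v, c in self.assignment.items():
            out[c].append(v)
        return [sorted(c, key=str) for c in out]


@dataclass
class Dendrogram:
    """Record of the divisive run: removal order and the split sequence."""

    removal_order: list[Edge]
    splits: list[tuple[Partition, float]]
    rng_seed: int


@dataclass
class CommunitySet:
    """The optimal cut: partition, its modularity, and the vertex lists."""

    partition: Partition
    q_max: float
    communities: list[list[Hashable]]

    @property
    def n_communities(self) -> int:
        return self.partition.k


def edge_betweenness(net: InteractionNetwork) -> dict[Edge, float]:
    """Betweenness of every edge over unordered vertex pairs.

    Multiple shortest paths between a pair contribute equal fractional
    weight summing to 1 per pair. Keys are edges with endpoints ordered as
    (min, max) by string.
    """
    raw = nx.edge_betweenness_centrality(net.graph, normalized=False)
    return {_canon(e): float(b) for e, b in raw.items()}


def _canon(edge: Edge) -> Edge:
    u, v = edge
    return (u, v) if str(u) <= str(v) else (v, u)


def modularity(partition: Partition, net: InteractionNetwork) -> float:
    """Q = Tr(e) - sum_i a_i^2 against the network's full edge set."""
    m = net.graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for a network with no edges")
    uncovered = [v for v in net.graph.nodes if v not in partition.assignment]
    if uncovered:
        raise ValueError(f"partition does not cover vertices: {uncovered[:5]}")
    k = partition.k
    e = np.zeros((k, k))
    for u, v in net.graph.edges():
        i, j = partition.assignment[u], partition.assignment[v]
        if i == j:
            e[i, i] += 1.0
        else:
            e[i, j] += 0.5
            e[j, i] += 0.5
    e /= m
    a = e.sum(axis=1)
    return float(np.trace(e) - np.sum(a * a))


def ng_dendrogram(net: InteractionNetwork, seed: int) -> Dendrogram:
    """Run the divisive loop to exhaustion, recording every split.

    Disconnected input is accepted: its initial components form the first
    recorded partition before any removal. Q is always evaluated against
    the original edge set. Same graph and seed give an identical removal
    order.
    """
    original = net
    g = net.graph.copy()
    rng = random.Random(seed)
    removal_order: list[Edge] = []
    splits: list[tuple[Partition, float]] = []

    n_comp = nx.number_connected_components(g) if g.number_of_nodes() else 0
    if n_comp > 1:
        part = Partition.from_components(g)
        splits.append((part, modularity(part, original)))

    while g.number_of_edges() > 0:
        bt = nx.edge_betweenness_centrality(g, normalized=False)
        b_max = max(bt.values())
        ties = sorted(
            (_canon(e) for e, b in bt.items()
             if math.isclose(b, b_max, rel_tol=_TIE_RTOL, abs_tol=1e-12)),
            key=lambda e: (str(e[0]), str(e[1])),
        )
        edge = ties[rng.randrange(len(ties))] if len(ties) > 1 else ties[0]
        g.remove_edge(*edge)
        removal_order.append(edge)
        c = nx.number_connected_components(g)
        if c > n_comp:
            n_comp = c
            part = Partition.from_components(g)
            splits.append((part, modularity(part, original)))

    return Dendrogram(removal_order=removal_order, splits=splits, rng_seed=seed)


def best_partition(dendro: Dendrogram) -> CommunitySet:
    """Pick the recorded split with maximal Q (ties: fewest communities)."""
    if not dendro.splits:
        raise ValueError("dendrogram has no recorded splits")
    best_idx = 0
    best_q = dendro.splits[0][1]
    for i, (_, q) in enumerate(dendro.splits):
        if q > best_q:
            best_idx, best_q = i, q
    part = dendro.splits[best_idx][0]
    return CommunitySet(partition=part, q_max=best_q, communities=part.communities())


def write_communities_tsv(cs: CommunitySet, path: str | Path) -> None:
    rows = sorted(
        ((str(v), c) for v, c in cs.partition.assignment.items()),
        key=lambda r: (r[1], r[0]),
    )
    pd.DataFrame(rows, columns=["gene", "community_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_summary_json(cs: CommunitySet, seed: int, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"n_communities": cs.n_communities, "q_max": cs.q_max, "seed": seed},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
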