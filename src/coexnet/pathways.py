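"""Pathway projection of condition-specific community sub-networks.

A community of the reference-condition network is reduced to the genes
absent from the comparison network, and the induced gene graph is projected
onto pathway space: each annotated gene keeps a single pathway chosen by
the maximum spanning pathway reduction heuristic (among its candidate
pathways, the one shared by the most *other* annotated genes of the
sub-network; ties broken by smallest pathway id). The resulting Pathway
Projection Network (PPN) has one node per assigned pathway, node size
(cardinality) = genes assigned, node degree = distinct neighbour pathways,
and edge weight = number of underlying gene-gene edges; intra-pathway gene
edges accumulate as node self-weights.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .network import InteractionNetwork

log = logging.getLogger(__name__)


@dataclass
class PathwayAnnotation:
    """Many-to-many gene -> pathway candidate map with display names."""

    gene_to_pathways: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayAnnotation":
        """Read a flat (gene, pathway_id[, pathway_name]) TSV."""
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: annotation needs >=2 columns (gene, pathway)")
        gp: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for row in df.itertuples(index=False):
            gene, pathway = str(row[0]), str(row[1])
            gp.setdefault(gene, set()).add(pathway)
            if len(row) > 2 and pd.notna(row[2]):
                names[pathway] = str(row[2])
        return cls({g: frozenset(p) for g, p in gp.items()}, names)

    def candidates(self, gene: str) -> frozenset[str]:
        return self.gene_to_pathways.get(gene, frozenset())


@dataclass
class PathwayAssignment:
    """One-to-one gene -> pathway restriction for one sub-network."""

    assignment: dict[str, str]
    unannotated: tuple[str, ...] = ()

    def pathways(self) -> set[str]:
        return set(self.assignment.values())


@dataclass
class PPNGraph:
    """Pathway-level projection of a gene sub-network.

    Node attributes: ``cardinality`` (genes assigned), ``degree`` (distinct
    neighbour pathways, self-links excluded), ``self_weight`` (intra-pathway
    gene edges). Edge attribute ``weight`` counts the underlying gene-gene
    edges between the two pathways.
    """

    graph: nx.Graph
    n_assigned_genes: int
    n_gene_edges_assigned: int

    def binarized(self) -> nx.Graph:
        """Same topology with all edge weights collapsed to 1."""
        g = self.graph.copy()
        for _, _, d in g.edges(data=True):
            d["weight"] = 1
        return g


def condition_specific_subnetwork(
    community: Iterable[str],
    net_a: InteractionNetwork,
    net_b: InteractionNetwork,
) -> InteractionNetwork:
    """Induced subgraph of ``net_a`` on community genes absent from ``net_b``."""
    community = set(community)
    outside = community - set(net_a.graph.nodes)
    if outside:
        raise ValueError(f"community genes not in reference network: {sorted(outside)[:5]}")
    keep = community - set(net_b.graph.nodes)
    sub = net_a.graph.subgraph(keep).copy()
    if not keep:
        log.warning("condition-specific sub-network is empty")
    return InteractionNetwork(graph=sub, tau=net_a.tau)


def filter_by_cardinality(
    subnets: Sequence[InteractionNetwork], min_n: int = 100
) -> list[InteractionNetwork]:
    """Keep sub-networks with >= min_n vertices, largest first (stable)."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    kept = [s for s in subnets if s.n_vertices >= min_n]
    return sorted(kept, key=lambda s: -s.n_vertices)


def reduce_pathways(
    subnet: InteractionNetwork, ann: PathwayAnnotation
) -> PathwayAssignment:
    """Collapse each gene's candidate pathways to one by maximum spanning.

    For gene g the chosen pathway maximizes the number of *other* annotated
    genes of the sub-network whose candidate set also contains it; ties go
    to the lexicographically smallest pathway id. Unannotated genes are
    skipped and counted. The result is independent of gene input order.
    """
    genes = sorted(subnet.graph.nodes, key=str)
    cands = {g: sorted(ann.candidates(g)) for g in genes}
    annotated = [g for g in genes if cands[g]]
    support = Counter(p for g in annotated for p in cands[g])
    # support[p] counts g itself whenever p is one of g's candidates, so
    # "other genes" = support[p] - 1; the -1 is uniform over g's candidates
    # and cannot change the argmax, but is kept for clarity.
    assignment = {
        g: min(cands[g], key=lambda p: (-(support[p] - 1), p)) for g in annotated
    }
    unannotated = tuple(g for g in genes if not cands[g])
    if unannotated:
        log.info("reduce_pathways: %d unannotated genes skipped", len(unannotated))
    return PathwayAssignment(assignment=assignment, unannotated=unannotated)


def build_ppn(subnet: InteractionNetwork, assign: PathwayAssignment) -> PPNGraph:
    """Contract assigned genes into pathway nodes, counting gene edges."""
    card = Counter(assign.assignment.values())
    g = nx.Graph()
    for pathway, n in sorted(card.items()):
        g.add_node(pathway, cardinality=int(n), self_weight=0)
    n_edges_assigned = 0
    for u, v in subnet.graph.edges():
        pu = assign.assignment.get(u)
        pv = assign.assignment.get(v)
        if pu is None or pv is None:
            continue
        n_edges_assigned += 1
        if pu == pv:
            g.nodes[pu]["self_weight"] += 1
        elif g.has_edge(pu, pv):
            g[pu][pv]["weight"] += 1
        else:
            g.add_edge(pu, pv, weight=1)
    for p in g.nodes:
        g.nodes[p]["degree"] = g.degree(p)
    return PPNGraph(
        graph=g,
        n_assigned_genes=sum(card.values()),
        n_gene_edges_assigned=n_edges_assigned,
    )


def top_pairs(
    subnet: InteractionNetwork,
    assign: PathwayAssignment,
    pathway_a: str,
    pathway_b: str,
    k: int = 5,
) -> pd.DataFrame:
    """Top-|r| gene pairs bridging two pathways of a sub-network.

    Returns a DataFrame (gene_a, pathway_a, gene_b, pathway_b, score) with
    gene_a assigned to ``pathway_a``, sorted by |score| descending, ties by
    lexicographic gene pair, truncated to k rows.
    """
    present = assign.pathways()
    for p in (pathway_a, pathway_b):
        if p not in present:
            raise ValueError(f"pathway '{p}' has no assigned genes in this sub-network")
    rows = []
    for u, v, d in subnet.graph.edges(data=True):
        pu = assign.assignment.get(u)
        pv = assign.assignment.get(v)
        if pu is None or pv is None:
            continue
        if {pu, pv} != {pathway_a, pathway_b}:
            continue
        if pu == pathway_a:
            a, b = u, v
        else:
            a, b = v, u
        if pathway_a == pathway_b and str(a) > str(b):
            a, b = b, a
        rows.append((str(a), pathway_a, str(b), pathway_b, float(d.get("weight", 1.0))))
    rows.sort(key=lambda r: (-abs(r[4]), r[0], r[2]))
    df = pd.DataFrame(
        rows, columns=["gene_a", "pathway_a", "gene_b", "pathway_b", "score"]
    )
    return df.head(k).reset_index(drop=True)


def pathway_gene_counts(
    assign: PathwayAssignment, pathway_ids: Sequence[str]
) -> dict[str, int]:
    """Assigned-gene count per queried pathway id (0 when absent)."""
    card = Counter(assign.assignment.values())
    return {p: int(card.get(p, 0)) for p in pathway_ids}


# ---------------------------------------------------------------------------
# writers

def write_ppn_graphml(ppn: PPNGraph, path: str | Path) -> None:
    nx.write_graphml(ppn.graph, str(path))


def write_ppn_sif(ppn: PPNGraph, path: str | Path) -> None:
    """Simple interaction format for Cytoscape import (pp relation)."""
    lines = []
    for u, v in sorted((sorted((str(a), str(b))) for a, b in ppn.graph.edges())):
        lines.append(f"{u}\tpp\t{v}")
    for n in sorted(ppn.graph.nodes, key=str):
        if ppn.graph.degree(n) == 0:
            lines.append(str(n))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
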