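"""Derived interaction networks from expression correlation.

A derived interaction network places an undirected edge between two genes
whenever the absolute Pearson correlation of their expression profiles
across samples strictly exceeds a threshold tau (0.8 by default, matching
the convention that |r| > 0.8 is a strong correlation). Edges carry the
signed correlation as weight, but all downstream graph algorithms treat the
network as unweighted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ParseError
from .expression import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over genes.

    ``undefined`` flags genes with zero variance across samples: their
    correlations are undefined (NaN in ``r``) and they never form edges.
    """

    gene_ids: list[str]
    r: np.ndarray
    undefined: np.ndarray  # bool per gene

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.r.shape != (n, n):
            raise ValueError(f"r must be {n}x{n}, got {self.r.shape}")


@dataclass
class InteractionNetwork:
    """Thresholded gene graph; vertices are genes incident to >=1 edge."""

    graph: nx.Graph
    tau: float
    isolated: tuple[str, ...] = ()

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkStats:
    """Global topology panel of an interaction network.

    Conventions: clustering is the mean local clustering coefficient
    (degree < 2 contributes 0); diameter is the maximum and radius the
    minimum, over connected components, of the component diameter/radius;
    characteristic path length averages shortest-path distances over
    connected pairs only; pct_shortest_paths is the fraction of ordered
    vertex pairs that are connected; centralization is Freeman degree
    centralization; heterogeneity is the coefficient of variation of the
    degree distribution.
    """

    n_vertices: int
    n_edges: int
    density: float
    avg_degree: float
    avg_neighbors: float
    clustering_coefficient: float
    n_components: int
    diameter: int
    radius: int
    centralization: float
    pct_shortest_paths: float
    characteristic_path_length: float
    heterogeneity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Vertices": self.n_vertices,
            "Edges": self.n_edges,
            "Clustering coefficient": self.clustering_coefficient,
            "Connected components": self.n_components,
            "Network diameter": self.diameter,
            "Network radius": self.radius,
            "Network centralization": self.centralization,
            "Shortest paths": self.pct_shortest_paths,
            "Characteristic path length": self.characteristic_path_length,
            "Avg. number of neighbors": self.avg_neighbors,
            "Network density": self.density,
            "Network heterogeneity": self.heterogeneity,
        }


def correlation_matrix(expr: ExpressionMatrix) -> CorrelationMatrix:
    """Pearson correlation between every pair of genes, across samples.

    Zero-variance genes are flagged undefined (NaN row/column) rather than
    raising; they are excluded from edge formation downstream.
    """
    if expr.n_samples < 2:
        raise ValueError("correlation requires at least 2 samples")
    x = expr.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    undefined = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    r[undefined, :] = np.nan
    r[:, undefined] = np.nan
    defined = ~undefined
    r[np.ix_(defined, defined)] = np.clip(r[np.ix_(defined, defined)], -1.0, 1.0)
    r[np.diag_indices_from(r)] = np.where(undefined, np.nan, 1.0)
    return CorrelationMatrix(gene_ids=expr.gene_ids, r=r, undefined=undefined)


def build_network(corr: CorrelationMatrix, tau: float = 0.8) -> InteractionNetwork:
    """Threshold a correlation matrix into an interaction network.

    Edge (i, j) iff |r_ij| > tau strictly, i != j, both genes with defined
    correlation. Genes left without any edge are dropped from the vertex
    set and recorded in ``isolated``.
    """
    if not (0.0 <= tau < 1.0):
        raise ValueError(f"tau must be in [0, 1), got {tau}")
    n = len(corr.gene_ids)
    g = nx.Graph()
    iu, ju = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore"):
        keep = np.abs(corr.r[iu, ju]) > tau
    keep &= ~np.isnan(corr.r[iu, ju])
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(corr.gene_ids[i], corr.gene_ids[j], weight=float(corr.r[i, j]))
    connected = set(g.nodes)
    isolated = tuple(gid for gid in corr.gene_ids if gid not in connected)
    log.info(
        "build_network(tau=%g): %d vertices, %d edges, %d isolated genes dropped",
        tau, g.number_of_nodes(), g.number_of_edges(), len(isolated),
    )
    return InteractionNetwork(graph=g, tau=tau, isolated=isolated)


def largest_component(net: InteractionNetwork) -> InteractionNetwork:
    """Induced subgraph on the largest connected component.

    Ties on size are broken in favour of the component containing the
    lexicographically smallest vertex id.
    """
    if net.n_vertices == 0:
        raise ValueError("largest_component of an empty network")
    comps = [sorted(c, key=str) for c in nx.connected_components(net.graph)]
    best = min(comps, key=lambda c: (-len(c), str(c[0])))
    sub = net.graph.subgraph(best).copy()
    return InteractionNetwork(graph=sub, tau=net.tau)


def network_stats(net: InteractionNetwork) -> NetworkStats:
    """Compute the global statistics panel for a nonempty network."""
    g = net.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        raise ValueError("network_stats of an empty network")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    avg_degree = 2.0 * m / n
    clustering = nx.average_clustering(g) if n > 1 else 0.0

    comps = list(nx.connected_components(g))
    diam = 0
    radius = 0
    sum_dist = 0
    n_conn_pairs = 0  # ordered
    eccs_min: list[int] = []
    for comp in comps:
        sub = g.subgraph(comp)
        if len(comp) == 1:
            eccs_min.append(0)
            continue
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        ecc = {u: max(d.values()) for u, d in dist.items()}
        diam = max(diam, max(ecc.values()))
        eccs_min.append(min(ecc.values()))
        sum_dist += sum(sum(d.values()) for d in dist.values())  # ordered pairs
        n_conn_pairs += len(comp) * (len(comp) - 1)
    radius = min(eccs_min) if eccs_min else 0
    cpl = sum_dist / n_conn_pairs if n_conn_pairs else 0.0
    pct_paths = n_conn_pairs / (n * (n - 1)) if n > 1 else 0.0

    if n > 2:
        centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density)
    else:
        centralization = 0.0
    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0

    return NetworkStats(
        n_vertices=n,
        n_edges=m,
        density=density,
        avg_degree=avg_degree,
        avg_neighbors=avg_degree,
        clustering_coefficient=float(clustering),
        n_components=len(comps),
        diameter=int(diam),
        radius=int(radius),
        centralization=float(centralization),
        pct_shortest_paths=float(pct_paths),
        characteristic_path_length=float(cpl),
        heterogeneity=heterogeneity,
    )


# ---------------------------------------------------------------------------
# readers / writers

def write_edgelist(net: InteractionNetwork, path: str | Path) -> None:
    """Write a (gene_a, gene_b, r) TSV edge list."""
    rows = sorted(
        (min(str(u), str(v)), max(str(u), str(v)), d.get("weight", 1.0))
        for u, v, d in net.graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"]).to_csv(
        path, sep="\t", index=False
    )


def read_edgelist(path: str | Path, tau: float = 0.8) -> InteractionNetwork:
    """Read the edge-list TSV dialect written by :func:`write_edgelist`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    expected = {"gene_a", "gene_b", "r"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: edge list needs columns {sorted(expected)}")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, weight=float(row.r))
    return InteractionNetwork(graph=g, tau=tau)


def write_graphml(net: InteractionNetwork, path: str | Path) -> None:
    g = net.graph.copy()
    g.graph["tau"] = float(net.tau)
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> InteractionNetwork:
    g = nx.read_graphml(str(path))
    tau = float(g.graph.get("tau", 0.8))
    g = nx.Graph(g)
    return InteractionNetwork(graph=g, tau=tau)
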