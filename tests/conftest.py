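from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexnet import ExpressionMatrix, InteractionNetwork


def make_net(edges, tau: float = 0.8, weights=None) -> InteractionNetwork:
    """Build an InteractionNetwork from an edge list (optionally weighted)."""
    g = nx.Graph()
    for i, (u, v) in enumerate(edges):
        w = 1.0 if weights is None else weights[i]
        g.add_edge(u, v, weight=w)
    return InteractionNetwork(graph=g, tau=tau)


@pytest.fixture
def two_triangles_bridge() -> InteractionNetwork:
    """Two triangles {a,b,c} and {d,e,f} joined by the bridge c-d."""
    return make_net(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f"),
         ("c", "d")]
    )


@pytest.fixture
def path_net() -> InteractionNetwork:
    return make_net([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle_net() -> InteractionNetwork:
    return make_net([("a", "b"), ("b", "c"), ("a", "c")])


def make_expr(values, gene_ids=None, sample_ids=None, condition="normal"):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        conditions={s: condition for s in sample_ids},
    )


def write_tsv(path, text: str) -> str:
    path.write_text(text)
    return str(path)
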