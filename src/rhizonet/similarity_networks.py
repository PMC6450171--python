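"""Sample-similarity matrices, maximum spanning trees, and raw
bipartite presence networks.

Networks throughout the package are ``networkx.Graph`` objects with a
``role`` attribute on every node (``otu`` / ``sample`` /
``genotype-bin`` / ``property``), a ``weight`` and optional ``sign``
attribute on every edge, and a ``bipartite`` flag in ``G.graph`` when
edges span two roles.

Similarity is computed on Hellinger-transformed abundances by
default, matching the transform applied ahead of all multivariate
analyses; pass ``transform=None`` on raw input to opt out.
"""

from __future__ import annotations

import warnings

import numpy as np
import networkx as nx
import pandas as pd

from rhizonet.data_model import OtuTable, hellinger_transform


def _maybe_hellinger(table: OtuTable, transform: str | None) -> OtuTable:
    if transform == "hellinger" and table.scale in ("counts", "relative"):
        return hellinger_transform(table)
    return table


def pearson_similarity_matrix(table: OtuTable, axis: str = "samples",
                              transform: str | None = "hellinger") -> pd.DataFrame:
    """Pairwise Pearson correlation between samples (columns) or OTUs (rows).

    Constant vectors cannot be correlated; their entries are set to 0
    (with a warning) rather than NaN so downstream spanning trees stay
    connected.
    """
    table = _maybe_hellinger(table, transform)
    if axis == "samples":
        mat = table.values.T
        labels = table.sample_ids
    elif axis == "otus":
        mat = table.values
        labels = table.otu_ids
    else:
        raise ValueError(f"axis must be 'samples' or 'otus', got {axis!r}")
    if mat.shape[0] < 2 or mat.shape[1] < 3:
        raise ValueError("need >=2 vectors of length >=3 for correlation")
    sd = mat.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant vector(s); correlations set to 0",
            stacklevel=2,
        )
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=labels, columns=labels)


def proportional_similarity_matrix(table: OtuTable, axis: str = "samples") -> pd.DataFrame:
    """Proportional Similarity PS(p, q) = sum_i min(p_i, q_i) between samples.

    Columns are renormalized to proportions internally, so any input
    scale is accepted.  PS is 1 for identical composition profiles and
    0 for disjoint ones; all-zero samples get PS 0 against everything.
    """
    if axis != "samples":
        raise ValueError("proportional similarity is defined between samples")
    vals = table.values
    sums = vals.sum(axis=0)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero sample(s); PS set to 0", stacklevel=2)
    props = vals / np.where(zero, 1.0, sums)
    n = vals.shape[1]
    ps = np.zeros((n, n))
    for i in range(n):
        ps[i, i:] = np.minimum(props[:, i:i + 1], props[:, i:]).sum(axis=0)
        ps[i:, i] = ps[i, i:]
    ps[zero, :] = 0.0
    ps[:, zero] = 0.0
    np.fill_diagonal(ps, np.where(zero, 0.0, 1.0))
    return pd.DataFrame(ps, index=table.sample_ids, columns=table.sample_ids)


def maximum_spanning_tree(similarity: pd.DataFrame, role: str = "sample") -> nx.Graph:
    """Maximum spanning tree of a similarity matrix.

    Similarities s are converted to distances 1 - s and a minimum
    spanning tree (Kruskal) is built per connected component, which is
    the tree maximizing total similarity.  Ties are broken by
    lexicographic (u, v) edge order so trees are reproducible across
    platforms.
    """
    labels = list(similarity.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 nodes for a spanning tree")
    g = nx.Graph()
    for u in labels:
        g.add_node(u, role=role)
    for i, u in enumerate(labels):
        for v in labels[i + 1:]:
            s = float(similarity.at[u, v])
            if np.isfinite(s):
                g.add_edge(u, v, weight=s, distance=1.0 - s)
    sorted_edges = sorted(g.edges(data=True), key=lambda e: (e[2]["distance"], str(e[0]), str(e[1])))
    tree = nx.Graph()
    tree.add_nodes_from(g.nodes(data=True))
    uf = nx.utils.UnionFind(labels)
    for u, v, d in sorted_edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            tree.add_edge(u, v, weight=d["weight"], sign="+" if d["weight"] >= 0 else "-")
    return tree


def bipartite_presence_network(table: OtuTable) -> nx.Graph:
    """Bipartite OTU-sample network: edge wherever the OTU was observed.

    Edge weight carries the (possibly transformed) abundance value;
    presence itself is scale-invariant.
    """
    g = nx.Graph(bipartite=True)
    for o in table.otu_ids:
        g.add_node(o, role="otu")
    for s in table.sample_ids:
        g.add_node(s, role="sample")
    vals = table.values
    for i, o in enumerate(table.otu_ids):
        for j, s in enumerate(table.sample_ids):
            if vals[i, j] > 0:
                g.add_edge(o, s, weight=float(vals[i, j]), sign="none")
    return g
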