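"""OTU-OTU correlation networks, Markov clustering, and topology.

The co-occurrence pipeline is: drop OTUs seen in fewer than 3
samples, Pearson-correlate every OTU pair across all samples of the
experiment on Hellinger-scale values, keep |r| >= 0.6 as edges, then
cluster the network with the Markov Cluster (MCL) algorithm at
inflation 2.5.  MCL simulates flow on the graph by alternating
expansion (matrix squaring: flow spreads) and inflation (elementwise
powering + renormalization: strong flow is boosted, weak flow
decays); the attractor structure of the limit matrix yields a hard
partition.  MCL needs a non-negative stochastic matrix, so it runs on
|r| edge weights — the sign of each correlation is retained only as
edge metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
import pandas as pd

from rhizonet.data_model import OtuTable, TaxonomyTable, filter_min_occurrence
from rhizonet.similarity_networks import pearson_similarity_matrix


@dataclass(frozen=True)
class CommunityPartition:
    """OTU -> community label; label 0 marks singletons/background."""

    labels: dict[str, int]

    def members(self, label: int) -> list[str]:
        return sorted(o for o, c in self.labels.items() if c == label)

    def community_labels(self) -> list[int]:
        return sorted({c for c in self.labels.values() if c > 0})

    @property
    def n_communities(self) -> int:
        return len(self.community_labels())


def correlation_network(table: OtuTable, threshold: float = 0.6,
                        min_nonzero: int = 3,
                        transform: str | None = "hellinger") -> nx.Graph:
    """Absolute-Pearson OTU co-occurrence network.

    Nodes are OTUs retained by the min-occurrence filter; an
    undirected edge joins i, j iff |Pearson(row_i, row_j)| across all
    samples reaches ``threshold``.  Edges carry weight |r| and the
    sign of r.
    """
    if table.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate OTUs")
    filtered = filter_min_occurrence(table, min_nonzero)
    g = nx.Graph()
    for o in filtered.otu_ids:
        g.add_node(o, role="otu")
    if filtered.shape[0] < 2:
        return g
    r = pearson_similarity_matrix(filtered, axis="otus", transform=transform)
    rv = r.to_numpy()
    ids = filtered.otu_ids
    ii, jj = np.where(np.triu(np.abs(rv) >= threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(ids[i], ids[j], weight=float(abs(rv[i, j])),
                   sign="+" if rv[i, j] >= 0 else "-")
    return g


def _mcl_matrix(m: np.ndarray, inflation: float, expansion: int,
                max_iter: int, convergence_tol: float,
                prune_threshold: float) -> np.ndarray:
    """Iterate expansion/inflation on a column-stochastic matrix."""
    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = expanded ** inflation
        inflated[inflated < prune_threshold] = 0.0
        sums = inflated.sum(axis=0)
        sums[sums == 0] = 1.0
        new = inflated / sums
        if np.abs(new - m).max() < convergence_tol:
            return new
        m = new
    return m


def mcl_cluster(net: nx.Graph, inflation: float = 2.5, expansion: int = 2,
                max_iter: int = 200, convergence_tol: float = 1e-8,
                prune_threshold: float = 1e-6,
                self_loop_weight: float = 1.0) -> CommunityPartition:
    """Markov clustering of a non-negative weighted undirected graph.

    Self-loops of weight ``self_loop_weight`` are added, columns are
    normalized to a stochastic matrix, and expansion/inflation rounds
    run to a fixed point.  Rows of the limit matrix with positive
    diagonal mass seed clusters; every node joins the seed holding
    maximal limit-matrix mass in its column, ties to the lowest seed
    index.  Nodes left alone in their cluster get label 0
    (background); real communities are numbered 1.. in order of their
    lowest member.  Deterministic for a fixed graph.
    """
    nodes = sorted(net.nodes)
    if not nodes:
        return CommunityPartition(labels={})
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v, data in net.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError(
                f"negative weight on edge ({u!r}, {v!r}); cluster on absolute weights"
            )
        if u == v:
            continue
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    m[np.diag_indices(n)] = self_loop_weight
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    m = m / sums

    limit = _mcl_matrix(m, inflation, expansion, max_iter, convergence_tol, prune_threshold)

    # attractors: rows with any positive diagonal mass
    seeds = [i for i in range(n) if limit[i, i] > 0]
    if not seeds:  # degenerate fallback: every column's argmax seeds
        seeds = sorted(set(int(limit[:, j].argmax()) for j in range(n)))
    assign = np.empty(n, dtype=int)
    for j in range(n):
        mass = limit[seeds, j]
        best = int(np.argmax(mass))
        if mass[best] <= 0:
            assign[j] = j if j in seeds else seeds[0]
        else:
            assign[j] = seeds[best]
    # merge seeds that co-occur in one attractor system (share a member's mass)
    # union seeds appearing together in any column's positive support
    parent = {s: s for s in seeds}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(n):
        support = [s for s in seeds if limit[s, j] > 0]
        for s in support[1:]:
            ra, rb = find(support[0]), find(s)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    cluster_of = {}
    for j in range(n):
        cluster_of[nodes[j]] = find(assign[j])
    # relabel: singletons -> 0; communities numbered by lowest member index
    by_root: dict[int, list[str]] = {}
    for node, root in cluster_of.items():
        by_root.setdefault(root, []).append(node)
    labels: dict[str, int] = {}
    next_label = 1
    for root in sorted(by_root, key=lambda r: min(idx[x] for x in by_root[r])):
        members = by_root[root]
        if len(members) == 1:
            labels[members[0]] = 0
        else:
            for node in members:
                labels[node] = next_label
            next_label += 1
    return CommunityPartition(labels=labels)


def topology_measures(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, clustering, topological coefficient, betweenness.

    Clustering coefficient: fraction of neighbor pairs that are
    themselves adjacent (0 for degree < 2).  Topological coefficient
    of node n: mean over nodes m sharing at least one neighbor with n
    of J(n, m) / k(n), where J counts shared neighbors plus 1 if n and
    m are adjacent (0 for degree < 2).  Betweenness is unnormalized
    shortest-path betweenness with even splitting over equal-length
    paths.
    """
    nodes = sorted(net.nodes)
    deg = dict(net.degree())
    clust = nx.clustering(net)
    betw = nx.betweenness_centrality(net, normalized=False)
    adj = {n: set(net.neighbors(n)) - {n} for n in nodes}
    topo = {}
    for u in nodes:
        ku = len(adj[u])
        if ku < 2:
            topo[u] = 0.0
            continue
        partners = set()
        for w in adj[u]:
            partners.update(adj[w])
        partners.discard(u)
        js = []
        for m in sorted(partners):
            shared = len(adj[u] & adj[m])
            if shared == 0:
                continue
            js.append((shared + (1 if m in adj[u] else 0)) / ku)
        topo[u] = float(np.mean(js)) if js else 0.0
    return pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "clustering_coefficient": [float(clust[n]) for n in nodes],
            "topological_coefficient": [topo[n] for n in nodes],
            "betweenness_centrality": [float(betw[n]) for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def community_composition(partition: CommunityPartition,
                          taxonomy: TaxonomyTable) -> pd.DataFrame:
    """Fungal/bacterial make-up of every community.

    Returns one row per community (label > 0) with size, fungal and
    bacterial member counts, and a class of ``mixed`` /
    ``fungal-only`` / ``bacterial-only``.
    """
    rows = []
    for label in partition.community_labels():
        members = partition.members(label)
        n_f = n_b = 0
        for o in members:
            try:
                d = taxonomy.domain_of(o)
            except KeyError:
                raise ValueError(f"OTU {o!r} has no fungal/bacterial domain tag") from None
            if d == "fungal":
                n_f += 1
            else:
                n_b += 1
        cls = "mixed" if n_f and n_b else ("fungal-only" if n_f else "bacterial-only")
        rows.append((label, len(members), n_f, n_b, cls))
    return pd.DataFrame(
        rows, columns=["community", "size", "n_fungal", "n_bacterial", "class"]
    )
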