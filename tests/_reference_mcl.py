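"""Independent dense MCL implementation used only as a test oracle.

Written separately from the library version: plain loop, no pruning,
its own attractor interpretation (clusters = weakly connected
components of the limit matrix's nonzero structure).
"""

import numpy as np


def reference_mcl(adjacency: np.ndarray, inflation: float = 2.5,
                  expansion: int = 2, max_iter: int = 500,
                  tol: float = 1e-10) -> list[set[int]]:
    """Cluster a symmetric non-negative adjacency matrix; returns sets
    of node indices."""
    a = np.array(adjacency, dtype=float)
    n = a.shape[0]
    np.fill_diagonal(a, 1.0)
    m = a / a.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        m = m / m.sum(axis=0, keepdims=True)
        if np.abs(m - prev).max() < tol:
            break
    # interpret: connect i-j when column j puts mass on row i; take
    # weakly connected components of that bipartite-ish relation
    support = m > 1e-8
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(n):
        rows = np.where(support[:, j])[0]
        for i in rows:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, set[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(i)
    return list(clusters.values())
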