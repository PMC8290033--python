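"""Independent brute-force oracles for the graph-metric tests.

Deliberately naive: explicit Floyd-Warshall distances, explicit triangle
counting, per-pair loops.  These share no code with the package's metric
kernels, so agreement is a genuine cross-check.
"""

import numpy as np

INF = float("inf")


def fw_distances(adj):
    """All-pairs shortest paths by textbook Floyd-Warshall."""
    n = len(adj)
    D = [[0.0 if i == j else (1.0 if adj[i][j] else INF) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = D[i][k] + D[k][j]
                if via < D[i][j]:
                    D[i][j] = via
    return D


def nodal_clustering(adj, i):
    nbrs = [j for j in range(len(adj)) if adj[i][j]]
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(adj[a][b] for ai, a in enumerate(nbrs) for b in nbrs[ai + 1:])
    return 2.0 * links / (k * (k - 1))


def global_efficiency(adj):
    n = len(adj)
    if n < 2:
        return 0.0
    D = fw_distances(adj)
    total = sum(1.0 / D[i][j] for i in range(n) for j in range(n)
                if i != j and D[i][j] < INF)
    return total / (n * (n - 1))


def subgraph(adj, nodes):
    return [[adj[a][b] for b in nodes] for a in nodes]


def oracle_global(adj):
    """(aCp, aLp, aEg, aEloc) by brute force."""
    n = len(adj)
    aCp = sum(nodal_clustering(adj, i) for i in range(n)) / n
    D = fw_distances(adj)
    finite = [D[i][j] for i in range(n) for j in range(n) if i != j and D[i][j] < INF]
    aLp = sum(finite) / len(finite) if finite else float("nan")
    aEg = global_efficiency(adj)
    aEloc = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) >= 2:
            aEloc += global_efficiency(subgraph(adj, nbrs))
    aEloc /= n
    return aCp, aLp, aEg, aEloc


def oracle_nodal(adj):
    """dict of per-node aNCp, aNLp, aNe, aNLe, aDc arrays by brute force."""
    n = len(adj)
    D = fw_distances(adj)
    aNCp, aNLp, aNe, aNLe, aDc = [], [], [], [], []
    for i in range(n):
        aNCp.append(nodal_clustering(adj, i))
        reach = [D[i][j] for j in range(n) if j != i and D[i][j] < INF]
        aNLp.append(sum(reach) / len(reach) if reach else float("nan"))
        aNe.append(sum(1.0 / D[i][j] for j in range(n)
                       if j != i and D[i][j] < INF) / (n - 1))
        nbrs = [j for j in range(n) if adj[i][j]]
        aNLe.append(global_efficiency(subgraph(adj, nbrs)) if len(nbrs) >= 2 else 0.0)
        aDc.append(float(sum(adj[i])))
    return {"aNCp": np.array(aNCp), "aNLp": np.array(aNLp), "aNe": np.array(aNe),
            "aNLe": np.array(aNLe), "aDc": np.array(aDc)}


def random_adjacency(rng, n=16, p=0.5):
    a = rng.random((n, n)) < p
    a = np.triu(a, k=1)
    a = (a | a.T).astype(int)
    return a.tolist()
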