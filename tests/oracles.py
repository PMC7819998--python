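"""Independent brute-force oracles used by the tests.

Deliberately naive: Floyd–Warshall all-pairs distances and direct
transcriptions of the proximity/separation formulas, kept free of any
code path from the package under test.
"""

from __future__ import annotations

import itertools

import networkx as nx


def floyd_warshall(g: nx.Graph) -> dict:
    """All-pairs hop distances by the O(n^3) recurrence."""
    nodes = sorted(g.nodes(), key=str)
    inf = float("inf")
    d = {u: {v: (0 if u == v else inf) for v in nodes} for u in nodes}
    for u, v in g.edges():
        d[u][v] = d[v][u] = 1
    for k in nodes:
        for i in nodes:
            dik = d[i][k]
            if dik == inf:
                continue
            for j in nodes:
                alt = dik + d[k][j]
                if alt < d[i][j]:
                    d[i][j] = alt
    return d


def brute_proximity(dist: dict, a: set, b: set) -> float:
    """Direct transcription of the mean nearest-neighbor proximity,
    with self-exclusion when the two sets are equal."""
    same = set(a) == set(b)
    total = 0.0
    for x in a:
        targets = [y for y in b if not (same and y == x)]
        total += min(dist[x][y] for y in targets)
    for y in b:
        sources = [x for x in a if not (same and x == y)]
        total += min(dist[y][x] for x in sources)
    return total / (len(a) + len(b))


def brute_separation(dist: dict, a: set, b: set) -> float:
    return brute_proximity(dist, a, b) - (
        brute_proximity(dist, a, a) + brute_proximity(dist, b, b)
    ) / 2.0


def random_connected_graph(rng, n_max: int = 10) -> nx.Graph:
    """A random connected graph with 3..n_max nodes and string labels."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.25, 0.8))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})


def random_subset(rng, nodes: list, k_min: int = 2) -> set:
    k = int(rng.integers(k_min, max(k_min + 1, len(nodes))))
    idx = rng.choice(len(nodes), size=min(k, len(nodes)), replace=False)
    return {nodes[i] for i in idx}


def enumerate_lcc_sizes(g: nx.Graph, k: int) -> list[int]:
    """LCC size of every k-subset's induced subgraph (exhaustive null)."""
    out = []
    for combo in itertools.combinations(sorted(g.nodes(), key=str), k):
        sub = g.subgraph(combo)
        out.append(max(len(c) for c in nx.connected_components(sub)))
    return out
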