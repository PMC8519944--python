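"""Independent brute-force oracles shared across the test suite.

Everything here is deliberately naive (enumeration, power iteration,
networkx isomorphism) and independent of the implementation paths it
checks.
"""

from itertools import combinations

import networkx as nx
import numpy as np


def to_nx(net):
    cls = nx.DiGraph if net.directed else nx.Graph
    g = cls()
    g.add_nodes_from(range(net.n_nodes))
    g.add_edges_from(zip(*np.nonzero(net.adjacency)))
    return g


def brute_force_motif_counts(net, size):
    """Counts of connected induced ``size``-node subgraphs grouped by
    isomorphism, as a descending-sorted count list (class labels are
    implementation-specific, so censuses are compared as multisets)."""
    g = to_nx(net)
    connected = (nx.is_weakly_connected if net.directed else nx.is_connected)
    reps, counts = [], []
    for nodes in combinations(range(net.n_nodes), size):
        sub = g.subgraph(nodes)
        if sub.number_of_edges() == 0 or not connected(sub):
            continue
        for i, rep in enumerate(reps):
            if nx.is_isomorphic(sub, rep):
                counts[i] += 1
                break
        else:
            reps.append(nx.DiGraph(sub) if net.directed else nx.Graph(sub))
            counts.append(1)
    return sorted(counts, reverse=True)


def power_method_pagerank(adjacency, damping=0.85, iterations=50):
    """Plain fixed-iteration PageRank with uniform dangling redistribution
    over the other nodes."""
    a = np.asarray(adjacency, dtype=float).copy()
    n = a.shape[0]
    for i in range(n):
        if a[i].sum() == 0:
            a[i] = 1.0
            a[i, i] = 0.0
    P = a / a.sum(axis=1, keepdims=True)
    v = np.full(n, 1.0 / n)
    for _ in range(iterations):
        v = (1 - damping) / n + damping * (P.T @ v)
    return v


def best_two_community_modularity(adjacency):
    """Exhaustive modularity maximization over all 2-partitions (and the
    1-partition) of an undirected binary graph; returns the community count
    of the best partition found."""
    g = nx.from_numpy_array(np.asarray(adjacency))
    n = g.number_of_nodes()
    best_q, best_k = nx.community.modularity(g, [set(g.nodes())]), 1
    for mask in range(1, 2 ** (n - 1)):
        side = {i for i in range(n) if (mask >> i) & 1}
        other = set(range(n)) - side
        q = nx.community.modularity(g, [side, other])
        if q > best_q:
            best_q, best_k = q, 2
    return best_k


def uniform_attachment_max_degree(n, rng):
    """Grow a tree by uniform attachment; return its maximum degree."""
    deg = np.zeros(n, dtype=int)
    for new in range(1, n):
        t = rng.integers(new)
        deg[t] += 1
        deg[new] += 1
    return int(deg.max())


def naive_dd(n, divergence, rng):
    """Minimal independent duplication-divergence simulator (parent link
    probability 1); returns the adjacency."""
    a = np.zeros((n, n))
    a[0, 1] = a[1, 0] = 1.0
    for new in range(2, n):
        t = rng.integers(new)
        for j in np.flatnonzero(a[t, :new]):
            if rng.random() >= divergence:
                a[new, j] = a[j, new] = 1.0
        a[new, t] = a[t, new] = 1.0
    return a


def naive_niche(n, connectance, rng):
    """Minimal independent niche-model simulator; returns (adjacency, eta)
    with the diagonal zeroed."""
    eta = rng.random(n)
    x = rng.beta(1.0, (1 - 2 * connectance) / (2 * connectance), size=n)
    r = eta * x
    c = rng.uniform(r / 2, eta)
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and c[i] - r[i] / 2 <= eta[j] <= c[i] + r[i] / 2:
                a[i, j] = 1.0
    return a, eta
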