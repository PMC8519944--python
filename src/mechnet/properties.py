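"""Structural property profiles.

Each network is summarized by 18 components: 9 structural properties of the
raw network and the same 9 recomputed on its fifth-order row-normalized
Markov transform, which folds in indirect (multi-step) influence.

The nine properties are the in- and out-degree distributions, the Shannon
entropies of those distributions, global transitivity (clustering
coefficient), the PageRank distribution, the number of communities found by
greedy modularity maximization, and the censuses of connected 3-node and
4-node motifs by isomorphism class.

Distribution-valued components (degrees, PageRank) are stored as
descending-sorted per-node vectors, which makes every component a graph
invariant (unchanged under node relabeling).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import igraph as ig
import numpy as np

from .network import Network

#: The nine per-network property names, in profile order.
PROPERTY_NAMES = (
    "in_degree",
    "out_degree",
    "in_degree_entropy",
    "out_degree_entropy",
    "transitivity",
    "pagerank",
    "community_count",
    "motifs3",
    "motifs4",
)

#: All 18 component names: raw properties then their Markov counterparts.
COMPONENT_NAMES = PROPERTY_NAMES + tuple("markov_" + p for p in PROPERTY_NAMES)

#: Components whose values are vectors (everything else is a scalar).
VECTOR_COMPONENTS = frozenset(
    c for c in COMPONENT_NAMES
    if any(c.endswith(s) for s in ("in_degree", "out_degree", "pagerank",
                                   "motifs3", "motifs4")))

PAGERANK_DAMPING = 0.85
PAGERANK_TOL = 1e-10
PAGERANK_MAX_ITER = 200
MARKOV_ORDER = 5


@dataclass
class PropertyProfile:
    """The 18-component structural summary of one network."""

    n_nodes: int
    directed: bool
    components: dict

    def __getitem__(self, name):
        return self.components[name]


@lru_cache(maxsize=8)
def _connected_motif_classes(size: int, directed: bool) -> np.ndarray:
    """Indices of connected isomorphism classes in igraph's motif ordering.

    igraph reports NaN counts for disconnected classes; those positions are
    a structural constant of (size, directedness), probed here on a complete
    graph.  Undirected: 2 classes at size 3, 6 at size 4; directed: 13 and
    199 respectively.
    """
    g = ig.Graph.Full(size + 1, directed=directed)
    counts = np.array(g.motifs_randesu(size=size), dtype=float)
    return np.flatnonzero(~np.isnan(counts))


def motif_census(net: Network, size: int) -> np.ndarray:
    """Counts of connected induced subgraphs with ``size`` nodes, one entry
    per isomorphism class (igraph RAND-ESU exhaustive enumeration).

    The class ordering is igraph's canonical motif ordering restricted to
    connected classes.  Directed networks use directed classes (13 for
    size 3, 199 for size 4), undirected ones the undirected classes (2, 6).
    """
    if size not in (3, 4):
        raise ValueError("motif size must be 3 or 4")
    classes = _connected_motif_classes(size, net.directed)
    if net.n_nodes < size or net.n_edges == 0:
        return np.zeros(len(classes))
    g = _to_igraph_binary(net)
    counts = np.array(g.motifs_randesu(size=size), dtype=float)
    out = counts[classes]
    return np.nan_to_num(out, nan=0.0)


def _to_igraph_binary(net: Network) -> ig.Graph:
    a = (net.adjacency > 0)
    np.fill_diagonal(a, False)
    mode = "directed" if net.directed else "undirected"
    return ig.Graph.Adjacency(a, mode=mode)


def degree_vectors(net: Network):
    """(in, out) degree vectors, descending-sorted.

    For weighted networks these are strengths (column / row sums); for
    undirected networks the two vectors coincide.
    """
    a = net.adjacency
    out_deg = np.sort(a.sum(axis=1))[::-1]
    in_deg = np.sort(a.sum(axis=0))[::-1]
    return in_deg, out_deg


def degree_entropy(degrees) -> float:
    """Shannon entropy (nats) of the empirical distribution over distinct
    degree values (float degrees are grouped after rounding to 9 decimals)."""
    degrees = np.asarray(degrees, dtype=float)
    if degrees.size == 0:
        raise ValueError("empty degree vector")
    _, counts = np.unique(np.round(degrees, 9), return_counts=True)
    p = counts / counts.sum()
    return max(0.0, float(-(p * np.log(p)).sum()))


def transitivity(net: Network) -> float:
    """Global transitivity 3*triangles / connected triples, on the
    symmetrized binary graph; 0 when no triples exist."""
    g = _to_igraph_binary(net.symmetrized() if net.directed else net)
    return float(g.transitivity_undirected(mode="zero"))


def pagerank_vector(net: Network, damping: float = PAGERANK_DAMPING,
                    tol: float = PAGERANK_TOL,
                    max_iter: int = PAGERANK_MAX_ITER) -> np.ndarray:
    """Stationary distribution of the damped random walk with uniform
    teleportation, descending-sorted; dangling nodes redistribute uniformly
    over the other nodes.  Plain power iteration."""
    if not (0.0 < damping < 1.0):
        raise ValueError("damping must lie in (0, 1)")
    P = _row_stochastic(net.adjacency, net.directed)
    n = net.n_nodes
    v = np.full(n, 1.0 / n)
    base = (1.0 - damping) / n
    for _ in range(max_iter):
        nxt = base + damping * (P.T @ v)
        if np.abs(nxt - v).sum() < tol:
            v = nxt
            break
        v = nxt
    else:
        raise ArithmeticError(
            f"PageRank power iteration failed to converge in {max_iter} iterations")
    return np.sort(v)[::-1]


def community_count(net: Network) -> int:
    """Number of communities from deterministic greedy modularity
    maximization on the symmetrized binary graph; isolated nodes are
    singleton communities and components are never merged across."""
    g = _to_igraph_binary(net.symmetrized() if net.directed else net)
    if g.ecount() == 0:
        return net.n_nodes
    # greedy merging breaks ties by vertex and edge order, so cluster the
    # BLISS-canonical form rebuilt from its sorted edge list: the count is
    # then a true graph invariant
    g = g.permute_vertices(g.canonical_permutation())
    edges = sorted(tuple(sorted(e)) for e in g.get_edgelist())
    canon = ig.Graph(n=g.vcount(), edges=edges)
    dendro = canon.community_fastgreedy()
    return len(dendro.as_clustering())


def markov_transform(net: Network, order: int = MARKOV_ORDER) -> Network:
    """Row-normalized adjacency raised to ``order``.

    Zero rows (sinks) are replaced by uniform rows over all other nodes
    before powering, mirroring the PageRank dangling convention.  Every row
    of the result sums to 1.
    """
    if order < 1:
        raise ValueError("order must be a positive integer")
    P = _row_stochastic(net.adjacency, net.directed)
    Pk = np.linalg.matrix_power(P, order)
    return Network(Pk, directed=True)


def _row_stochastic(a: np.ndarray, directed: bool) -> np.ndarray:
    a = np.asarray(a, dtype=float).copy()
    n = a.shape[0]
    rows = a.sum(axis=1)
    dangling = rows == 0
    if np.any(dangling):
        a[dangling] = 1.0
        a[dangling, np.flatnonzero(dangling)] = 0.0  # uniform over *other* nodes
        rows = a.sum(axis=1)
    return a / rows[:, None]


def _binarized_markov(markov: Network) -> Network:
    """Binary directed view of a Markov transform: entries above 1/(2n)
    (half the uniform-row mass scale) become edges; diagonal dropped."""
    n = markov.n_nodes
    b = (markov.adjacency > 1.0 / (2.0 * n)).astype(float)
    np.fill_diagonal(b, 0.0)
    return Network(b, directed=True)


def _nine(net: Network, prefix: str = "") -> dict:
    """The nine property components of one (possibly weighted) network.

    For weighted (Markov) input the degree and PageRank components use the
    weights directly, while transitivity, communities and the motif census
    operate on the binarized graph.
    """
    binary = net.is_binary()
    census_net = net if binary else _binarized_markov(net)
    in_deg, out_deg = degree_vectors(net)
    return {
        prefix + "in_degree": in_deg,
        prefix + "out_degree": out_deg,
        prefix + "in_degree_entropy": degree_entropy(in_deg),
        prefix + "out_degree_entropy": degree_entropy(out_deg),
        prefix + "transitivity": transitivity(census_net),
        prefix + "pagerank": pagerank_vector(net),
        prefix + "community_count": float(community_count(census_net)),
        prefix + "motifs3": motif_census(census_net, 3),
        prefix + "motifs4": motif_census(census_net, 4),
    }


def property_profile(net: Network) -> PropertyProfile:
    """All 18 components: the nine properties of the raw network plus the
    same nine on its fifth-order Markov transform."""
    components = _nine(net)
    components.update(_nine(markov_transform(net), prefix="markov_"))
    return PropertyProfile(n_nodes=net.n_nodes, directed=net.directed,
                           components=components)
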