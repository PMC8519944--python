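"""Mixture-mechanism network generators.

A mixture network is one whose nodes are each governed by their own
generative mechanism.  Two construction processes are provided:

* growth — nodes arrive one at a time and wire into the existing network
  according to their mechanism's per-arrival rule;
* rewiring — a fully grown random network is repeatedly swept in random
  node order, each node redrawing its edges per its fixed mechanism rule.

Directionality is fixed per mechanism: ER, PA and NM act as directed rules
while DD and SW act as undirected rules (undirected edges are stored
symmetrically in a single directed adjacency).  The per-arrival rules reduce
to each mechanism's canonical wiring in the homogeneous limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import Network
from . import mechanisms as mech_mod
from .mechanisms import DEFAULT_PARAMETER_RANGES, DEFAULT_SECONDARY, MECHANISMS

#: Directionality of each mechanism's rule inside a mixture.
MIXTURE_DIRECTED = {"ER": True, "PA": True, "NM": True, "DD": False, "SW": False}


@dataclass
class MixtureSpec:
    """Ground truth of a mixture network: who wired how.

    ``assignments[i]`` is the mechanism governing node ``i`` and
    ``parameters[i]`` its governing-parameter value.  Nodes arrive (growth
    mode) in index order.
    """

    n_nodes: int
    assignments: Sequence[str]
    parameters: Sequence[float]
    process: str = "grow"
    sweeps: int = 10
    seed: Optional[int] = None
    secondary: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.assignments) != self.n_nodes or len(self.parameters) != self.n_nodes:
            raise ValueError("assignments and parameters must have length n_nodes")
        for m in self.assignments:
            if m not in MECHANISMS:
                raise ValueError(f"unknown mechanism {m!r}")
        if self.process not in ("grow", "rewire"):
            raise ValueError("process must be 'grow' or 'rewire'")
        for m in set(self.assignments):
            merged = dict(DEFAULT_SECONDARY.get(m, {}))
            merged.update(self.secondary.get(m, {}))
            self.secondary[m] = merged

    @property
    def proportions(self) -> dict:
        """Fraction of nodes governed by each mechanism present."""
        vals, counts = np.unique(np.asarray(self.assignments), return_counts=True)
        return {v: c / self.n_nodes for v, c in zip(vals, counts)}


def _rng_for(spec: MixtureSpec, rng) -> np.random.Generator:
    if rng is None:
        rng = spec.seed
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _undirected_link(a, i, j, on=True):
    a[i, j] = a[j, i] = 1.0 if on else 0.0


def _wire_arrival(a, new, spec: MixtureSpec, eta, rng):
    """Wire arriving node ``new`` into the existing 0..new-1 network."""
    mech = spec.assignments[new]
    p = spec.parameters[new]
    sec = spec.secondary.get(mech, {})
    existing = new  # nodes 0..new-1 exist

    if mech == "ER":
        # the arrival forms its own links: an out-arc to each existing node
        # independently with probability p (growth makes this a random DAG,
        # structurally unlike canonical ER)
        a[new, :existing] = (rng.random(existing) < p).astype(float)
    elif mech == "PA":
        deg = a[:existing, :existing].sum(axis=0)  # in-degree preference
        w = (deg + 1.0) ** p
        w = w / w.sum()
        m = min(int(sec.get("m", 1)), existing)
        targets = rng.choice(existing, size=m, replace=False, p=w)
        a[new, targets] = 1.0
    elif mech == "NM":
        beta_shape = (1.0 - 2.0 * p) / (2.0 * p)
        x = rng.beta(1.0, beta_shape)
        r = eta[new] * x
        c = rng.uniform(r / 2.0, eta[new])
        in_range = np.flatnonzero((eta[:existing] >= c - r / 2.0)
                                  & (eta[:existing] <= c + r / 2.0))
        a[new, in_range] = 1.0
    elif mech == "DD":
        template = rng.integers(existing)
        neigh = np.flatnonzero(np.maximum(a[template, :existing], a[:existing, template]))
        keep = neigh[rng.random(len(neigh)) >= p]
        for j in keep:
            _undirected_link(a, new, j)
        if rng.random() < float(sec.get("parent_link_prob", 1.0)):
            _undirected_link(a, new, template)
    elif mech == "SW":
        k = int(sec.get("k", 2))
        neighbours = list(range(max(0, existing - k), existing))  # most recent arrivals
        for j in neighbours:
            target = j
            if rng.random() < p:
                candidates = np.flatnonzero(
                    (np.maximum(a[new, :existing], a[:existing, new]) == 0))
                candidates = candidates[candidates != new]
                if len(candidates):
                    target = int(rng.choice(candidates))
            _undirected_link(a, new, target)


def make_mixture_grow(spec: MixtureSpec, rng=None) -> Network:
    """Grow a mixture network one node at a time.

    The seed is a connected 2-node network (a reciprocal pair); arrivals
    2..n-1 wire per their assigned mechanism's rule.  The result is stored
    as a directed adjacency with undirected edges symmetrized.
    """
    if spec.n_nodes < 3:
        raise ValueError("need at least 3 nodes to grow a mixture")
    rng = _rng_for(spec, rng)
    n = spec.n_nodes
    eta = np.empty(n)
    a = np.zeros((n, n))
    eta[0], eta[1] = rng.random(2)
    a[0, 1] = a[1, 0] = 1.0
    for new in range(2, n):
        eta[new] = rng.random()
        _wire_arrival(a, new, spec, eta, rng)
    np.fill_diagonal(a, 0.0)
    directed = not np.array_equal(a, a.T)
    return Network(a, directed=directed)


def _rewire_node(a, i, spec: MixtureSpec, eta, rng):
    n = spec.n_nodes
    mech = spec.assignments[i]
    p = spec.parameters[i]
    sec = spec.secondary.get(mech, {})
    others = np.arange(n) != i

    if mech == "ER":
        a[i, others] = (rng.random(n - 1) < p).astype(float)
    elif mech == "PA":
        a[i, :] = 0.0
        deg = a.sum(axis=0)
        deg[i] = 0.0
        w = (deg + 1.0) ** p
        w[i] = 0.0
        w = w / w.sum()
        a[i, rng.choice(n, p=w)] = 1.0
    elif mech == "NM":
        beta_shape = (1.0 - 2.0 * p) / (2.0 * p)
        x = rng.beta(1.0, beta_shape)
        r = eta[i] * x
        c = rng.uniform(r / 2.0, eta[i])
        a[i, :] = ((eta >= c - r / 2.0) & (eta <= c + r / 2.0)).astype(float)
        a[i, i] = 0.0
    elif mech == "DD":
        a[i, :] = 0.0
        a[:, i] = 0.0
        choices = np.flatnonzero(others)
        template = int(rng.choice(choices))
        neigh = np.flatnonzero(np.maximum(a[template], a[:, template]))
        neigh = neigh[neigh != i]
        keep = neigh[rng.random(len(neigh)) >= p]
        for j in keep:
            _undirected_link(a, i, j)
        if rng.random() < float(sec.get("parent_link_prob", 1.0)):
            _undirected_link(a, i, template)
    elif mech == "SW":
        a[i, :] = 0.0
        a[:, i] = 0.0
        k = int(sec.get("k", 2))
        for d in range(1, k + 1):
            for t in ((i + d) % n, (i - d) % n):
                target = t
                if rng.random() < p:
                    candidates = np.flatnonzero(
                        np.maximum(a[i], a[:, i]) == 0)
                    candidates = candidates[candidates != i]
                    if len(candidates):
                        target = int(rng.choice(candidates))
                _undirected_link(a, i, target)


def make_mixture_rewire(spec: MixtureSpec, sweeps: Optional[int] = None, rng=None,
                        initial_density: float = 0.2) -> Network:
    """Build a mixture by iterated rewiring of a fully grown random network.

    Starts from an undirected ER network at ``initial_density``; performs
    ``sweeps`` passes in which nodes, in a fresh random order each pass,
    redraw their incident edges per their fixed mechanism rule.
    """
    rng = _rng_for(spec, rng)
    if sweeps is None:
        sweeps = spec.sweeps
    n = spec.n_nodes
    start = mech_mod.simulate_er(n, initial_density, directed=False, rng=rng)
    a = start.adjacency.copy()
    eta = rng.random(n)
    for _ in range(sweeps):
        order = rng.permutation(n)
        for i in order:
            _rewire_node(a, i, spec, eta, rng)
    np.fill_diagonal(a, 0.0)
    directed = not np.array_equal(a, a.T)
    return Network(a, directed=directed)


def random_mixture(n: int, mechanisms: Sequence[str] = MECHANISMS, rng=None):
    """Draw a random mixture: simplex-uniform proportions over ``mechanisms``,
    one governing parameter per mechanism uniform in its admissible range,
    a shuffled node-to-mechanism assignment, grown with a fresh derived seed.

    Returns ``(spec, network)``; rebuilding from the returned spec (which
    records the seed) reproduces the network exactly.
    """
    if len(mechanisms) == 0:
        raise ValueError("need at least one mechanism")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    props = rng.dirichlet(np.ones(len(mechanisms)))
    # largest-remainder apportionment of n nodes to mechanisms
    raw = props * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    if rem > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
    params = {m: rng.uniform(*DEFAULT_PARAMETER_RANGES[m]) for m in mechanisms}
    assignments = [m for m, c in zip(mechanisms, counts) for _ in range(c)]
    assignments = [assignments[i] for i in rng.permutation(n)]
    seed = int(rng.integers(2 ** 31 - 1))
    spec = MixtureSpec(
        n_nodes=n,
        assignments=assignments,
        parameters=[params[m] for m in assignments],
        process="grow",
        seed=seed,
    )
    return spec, make_mixture_grow(spec)
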