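"""Simulators for the five candidate generative mechanisms.

Mechanisms
----------
ER  Erdos-Renyi random graph: every possible edge independently with
    probability ``p``.
DD  Duplication & Divergence: growth by copying a template node's links and
    deleting each copy with the divergence probability.
NM  Niche Model: directed food web; each consumer eats all species whose
    niche value falls in a contiguous diet interval.
PA  Preferential Attachment: growth where arriving nodes link to existing
    nodes with probability proportional to ``(degree + 1) ** power``.
SW  Small-World: ring lattice with ``k`` neighbours per side, each edge
    rewired with probability ``rewire_p``.

Each simulator varies a single governing parameter; remaining settings
(SW neighbourhood radius, PA edges per arrival, DD parent-link probability)
are fixed secondary settings carried on :class:`MechanismSpec`.

In addition to the canonical simulators, :func:`grow_network` builds every
mechanism through a standardized one-node-at-a-time growth process (the same
per-arrival rules used for mixture networks).  Growth itself imposes
structure, so grown ER/NM/SW networks are distributionally distinct from
their canonical counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import Network

MECHANISMS = ("ER", "DD", "NM", "PA", "SW")

#: Default grid-search range of each mechanism's governing parameter.
DEFAULT_PARAMETER_RANGES = {
    "ER": (0.01, 0.99),   # edge probability
    "DD": (0.01, 0.99),   # divergence (copied-edge deletion probability)
    "NM": (0.01, 0.49),   # connectance (beta shape undefined at C >= 0.5)
    "PA": (0.0, 4.0),     # attachment power
    "SW": (0.01, 0.99),   # rewiring probability
}

#: Fixed secondary settings (not searched by the classifier).
DEFAULT_SECONDARY = {
    "DD": {"parent_link_prob": 1.0},
    "PA": {"m": 1},
    "SW": {"k": 2},
}

#: Mechanisms with an inherently directed canonical form.
DIRECTED_CAPABLE = {"ER": (True, False), "PA": (True, False), "NM": (True,),
                    "DD": (False,), "SW": (False,)}


@dataclass
class MechanismSpec:
    """One candidate mechanism with its governing parameter.

    ``parameter`` is the single value the classifier's grid search varies
    (edge probability for ER, divergence for DD, connectance for NM,
    attachment power for PA, rewiring probability for SW).
    """

    mechanism: str
    parameter: float
    directed: bool = False
    parameter_range: Optional[tuple] = None
    secondary: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}")
        if self.parameter_range is None:
            self.parameter_range = DEFAULT_PARAMETER_RANGES[self.mechanism]
        lo, hi = self.parameter_range
        if not (lo <= self.parameter <= hi):
            raise ValueError(
                f"parameter {self.parameter} outside range [{lo}, {hi}] for {self.mechanism}")
        merged = dict(DEFAULT_SECONDARY.get(self.mechanism, {}))
        merged.update(self.secondary)
        self.secondary = merged

    def with_parameter(self, value: float) -> "MechanismSpec":
        return MechanismSpec(self.mechanism, value, self.directed,
                             self.parameter_range, dict(self.secondary))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_er(n: int, p: float, directed: bool = False, rng=None) -> Network:
    """Erdos-Renyi: each possible (off-diagonal) edge independently with probability p."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not (0.0 <= p <= 1.0):
        raise ValueError("edge probability must lie in [0, 1]")
    rng = _as_rng(rng)
    if directed:
        a = (rng.random((n, n)) < p).astype(float)
        np.fill_diagonal(a, 0.0)
    else:
        a = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        draws = (rng.random(len(iu[0])) < p).astype(float)
        a[iu] = draws
        a = a + a.T
    return Network(a, directed=directed)


def simulate_pa(n: int, power: float, directed: bool = False, m: int = 1, rng=None) -> Network:
    """Preferential attachment growth with kernel ``(degree + 1) ** power``.

    The seed is an ``m``-node clique (a single isolated node for m=1); each
    arriving node attaches ``m`` edges to distinct existing nodes drawn with
    probability proportional to ``(degree + 1) ** power`` (in-degree for the
    directed variant, where the new node's arcs point at its chosen targets).
    The +1 smoothing keeps zero-degree nodes reachable.
    """
    if power < 0:
        raise ValueError("attachment power must be >= 0")
    if m < 1 or m >= n:
        raise ValueError("need 1 <= m < n")
    rng = _as_rng(rng)
    a = np.zeros((n, n))
    seed = max(1, m)
    if seed > 1:  # connected starter clique
        a[:seed, :seed] = 1.0
        np.fill_diagonal(a, 0.0)
        if directed:  # clique stored as reciprocal arcs
            pass
    for new in range(seed, n):
        deg = a[:new, :new].sum(axis=0) if directed else a[:new, :new].sum(axis=1)
        w = (deg + 1.0) ** power
        w = w / w.sum()
        targets = rng.choice(new, size=min(m, new), replace=False, p=w)
        for t in targets:
            a[new, t] = 1.0
            if not directed:
                a[t, new] = 1.0
    return Network(a, directed=directed)


def simulate_dd(n: int, divergence: float, rng=None, parent_link_prob: float = 1.0) -> Network:
    """Duplication & Divergence growth (undirected).

    From a connected 2-node seed, each arriving node copies a uniformly
    chosen template's neighbourhood, deletes each copied edge independently
    with probability ``divergence``, and links to the template itself with
    probability ``parent_link_prob``.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must lie in [0, 1]")
    rng = _as_rng(rng)
    a = np.zeros((n, n))
    a[0, 1] = a[1, 0] = 1.0
    for new in range(2, n):
        template = rng.integers(new)
        neighbours = np.flatnonzero(a[template, :new])
        keep = neighbours[rng.random(len(neighbours)) >= divergence]
        a[new, keep] = 1.0
        a[keep, new] = 1.0
        if rng.random() < parent_link_prob:
            a[new, template] = a[template, new] = 1.0
    return Network(a, directed=False)


def niche_parameters(n: int, connectance: float, rng: np.random.Generator):
    """Draw (niche value, diet range, diet centre) triples for the niche model.

    eta_i ~ Uniform(0,1) (resampled until distinct), range r_i = eta_i * x with
    x ~ Beta(1, (1 - 2C) / (2C)), centre c_i ~ Uniform(r_i / 2, eta_i).
    """
    eta = rng.random(n)
    while len(np.unique(eta)) < n:  # probability-zero float-tie guard
        eta = rng.random(n)
    beta_shape = (1.0 - 2.0 * connectance) / (2.0 * connectance)
    x = rng.beta(1.0, beta_shape, size=n)
    r = eta * x
    c = rng.uniform(r / 2.0, eta)
    return eta, r, c


def simulate_nm(n: int, connectance: float, rng=None, return_params: bool = False):
    """Niche Model food web (directed; arc i -> j means i consumes j).

    With ``return_params`` also returns the drawn ``(eta, r, c)`` niche
    values, diet ranges and diet centres.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not (0.0 < connectance < 0.5):
        raise ValueError("connectance must lie in (0, 0.5)")
    rng = _as_rng(rng)
    eta, r, c = niche_parameters(n, connectance, rng)
    lo = c - r / 2.0
    hi = c + r / 2.0
    a = ((eta[None, :] >= lo[:, None]) & (eta[None, :] <= hi[:, None])).astype(float)
    np.fill_diagonal(a, 0.0)  # no cannibalism in this representation
    net = Network(a, directed=True)
    return (net, (eta, r, c)) if return_params else net


def simulate_sw(n: int, rewire_p: float, k: int = 2, rng=None) -> Network:
    """Watts-Strogatz small world (undirected), edge count exactly ``n * k``.

    Ring lattice connecting each node to its ``k`` nearest neighbours on each
    side; every lattice edge is rewired with probability ``rewire_p`` to a
    uniformly chosen non-duplicate, non-self target.
    """
    if n <= 2 * k:
        raise ValueError("need n > 2k")
    if not (0.0 <= rewire_p <= 1.0):
        raise ValueError("rewiring probability must lie in [0, 1]")
    rng = _as_rng(rng)
    a = np.zeros((n, n))
    for j in range(1, k + 1):
        for i in range(n):
            a[i, (i + j) % n] = a[(i + j) % n, i] = 1.0
    for j in range(1, k + 1):
        for i in range(n):
            t = (i + j) % n
            if a[i, t] and rng.random() < rewire_p:
                free = np.flatnonzero(a[i] == 0)
                free = free[free != i]
                if len(free) == 0:
                    continue  # node saturated; keep the lattice edge
                w = rng.choice(free)
                a[i, t] = a[t, i] = 0.0
                a[i, w] = a[w, i] = 1.0
    return Network(a, directed=False)


def simulate_mechanism(spec: MechanismSpec, n: int, rng=None) -> Network:
    """Dispatch to the canonical simulator for ``spec.mechanism``.

    Directedness handling: ER and PA support both orientations natively; NM
    is directed-only; DD and SW are undirected processes whose "directed"
    form is the same symmetric adjacency flagged directed (reciprocal arcs).
    """
    rng = _as_rng(rng)
    mech = spec.mechanism
    if mech == "ER":
        return simulate_er(n, spec.parameter, spec.directed, rng)
    if mech == "PA":
        return simulate_pa(n, spec.parameter, spec.directed,
                           m=int(spec.secondary.get("m", 1)), rng=rng)
    if mech == "NM":
        if not spec.directed:
            raise ValueError("the niche model is directed-only")
        return simulate_nm(n, spec.parameter, rng)
    if mech == "DD":
        net = simulate_dd(n, spec.parameter, rng,
                          parent_link_prob=float(spec.secondary.get("parent_link_prob", 1.0)))
    elif mech == "SW":
        net = simulate_sw(n, spec.parameter, k=int(spec.secondary.get("k", 2)), rng=rng)
    else:  # pragma: no cover
        raise ValueError(f"unknown mechanism {mech!r}")
    if spec.directed:  # symmetric adjacency viewed as reciprocal arcs
        return Network(net.adjacency, directed=True)
    return net


def grow_network(spec: MechanismSpec, n: int, rng=None) -> Network:
    """Standardized growth form: one node arrives at a time and wires per
    ``spec``'s per-arrival rule (the homogeneous case of a mixture network).

    Identical to the canonical simulator for PA and DD (inherently growth
    processes, so they delegate directly); distinct for ER, NM and SW.
    """
    from .mixtures import MixtureSpec, make_mixture_grow

    if spec.mechanism in ("PA", "DD"):
        return simulate_mechanism(spec, n, _as_rng(rng))

    mix = MixtureSpec(
        n_nodes=n,
        assignments=[spec.mechanism] * n,
        parameters=[spec.parameter] * n,
        secondary={spec.mechanism: dict(spec.secondary)},
    )
    net = make_mixture_grow(mix, rng=_as_rng(rng))
    if not spec.directed and net.directed:
        return net.symmetrized()
    return net
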