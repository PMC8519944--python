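"""Network state space: stacked-property distances and ordination.

The distance between two networks is a weighted average of per-component
Euclidean distances over their 18-component property profiles.  The weights
are the absolute loadings of each component on the first principal axis of
a PCA across a calibration panel simulated from all candidate mechanisms
("stacking ensemble").  The full pairwise distance matrix over a set of
networks constitutes a network state space; nearby networks have similar
structure and tend to share a generative mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .network import Network
from .properties import (COMPONENT_NAMES, VECTOR_COMPONENTS, PropertyProfile,
                         property_profile)
from . import mechanisms as mech


@dataclass
class StackWeights:
    """Per-component stacking weights: 18 nonnegative reals summing to 1."""

    weights: np.ndarray  # ordered as COMPONENT_NAMES
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(COMPONENT_NAMES),):
            raise ValueError(f"expected {len(COMPONENT_NAMES)} weights")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        s = self.weights.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def as_dict(self) -> dict:
        return dict(zip(COMPONENT_NAMES, self.weights.tolist()))

    def save(self, path):
        with open(path, "w") as fh:
            json.dump({"weights": self.as_dict(), "provenance": self.provenance},
                      fh, indent=2)

    @classmethod
    def load(cls, path) -> "StackWeights":
        with open(path) as fh:
            payload = json.load(fh)
        w = np.array([payload["weights"][c] for c in COMPONENT_NAMES])
        return cls(w, payload.get("provenance", {}))

    @classmethod
    def uniform(cls) -> "StackWeights":
        k = len(COMPONENT_NAMES)
        return cls(np.full(k, 1.0 / k), {"kind": "uniform"})


@dataclass
class StateSpace:
    """A set of networks (held as profiles), stacking weights, and the
    symmetric pairwise distance matrix ``D`` among them."""

    profiles: list
    weights: StackWeights
    D: np.ndarray


def _as_profile(obj) -> PropertyProfile:
    return obj if isinstance(obj, PropertyProfile) else property_profile(obj)


def _component_vector(profile: PropertyProfile, component: str) -> np.ndarray:
    """The comparison vector of one component: scalar -> length-1 array,
    motif counts normalized by the number of size-appropriate node subsets."""
    v = np.atleast_1d(np.asarray(profile[component], dtype=float))
    if component.endswith("motifs3"):
        return v / comb(profile.n_nodes, 3)
    if component.endswith("motifs4"):
        return v / comb(profile.n_nodes, 4)
    return v


def _padded(a: np.ndarray, length: int) -> np.ndarray:
    if len(a) == length:
        return a
    out = np.zeros(length)
    out[: len(a)] = a
    return out


def component_distance(profile_i, profile_j, component: str) -> float:
    """Euclidean distance between one component of two profiles.

    Scalars compare as absolute difference; sorted vectors are zero-padded
    to a common length; motif count vectors are normalized by C(n,3) or
    C(n,4) first so differently sized networks are commensurable.
    """
    if component not in COMPONENT_NAMES:
        raise ValueError(f"unknown component {component!r}")
    a = _component_vector(_as_profile(profile_i), component)
    b = _component_vector(_as_profile(profile_j), component)
    L = max(len(a), len(b))
    return float(np.linalg.norm(_padded(a, L) - _padded(b, L)))


def network_distance(net_i, net_j, weights: Optional[StackWeights] = None) -> float:
    """Stacked distance: weighted average of the 18 component distances."""
    if weights is None:
        weights = default_weights()
    pi, pj = _as_profile(net_i), _as_profile(net_j)
    return float(sum(w * component_distance(pi, pj, c)
                     for c, w in zip(COMPONENT_NAMES, weights.weights)))


def _component_matrix(profiles: Sequence[PropertyProfile], component: str,
                      length: int) -> np.ndarray:
    m = np.zeros((len(profiles), length))
    for i, p in enumerate(profiles):
        v = _component_vector(p, component)
        m[i, : len(v)] = v
    return m


def distance_matrix(profiles_a, profiles_b=None,
                    weights: Optional[StackWeights] = None) -> np.ndarray:
    """Vectorized stacked distances between two profile collections
    (pairwise within one collection when ``profiles_b`` is None)."""
    if weights is None:
        weights = default_weights()
    profiles_a = [_as_profile(p) for p in profiles_a]
    symmetric = profiles_b is None
    profiles_b = profiles_a if symmetric else [_as_profile(p) for p in profiles_b]
    D = np.zeros((len(profiles_a), len(profiles_b)))
    for c, w in zip(COMPONENT_NAMES, weights.weights):
        if w == 0.0:
            continue
        L = max(max(len(np.atleast_1d(p[c])) for p in profiles_a),
                max(len(np.atleast_1d(p[c])) for p in profiles_b))
        A = _component_matrix(profiles_a, c, L)
        B = A if symmetric else _component_matrix(profiles_b, c, L)
        D += w * cdist(A, B)
    return D


def build_state_space(networks, weights: Optional[StackWeights] = None) -> StateSpace:
    """Profile every network and assemble the full symmetric pairwise
    distance matrix."""
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    if weights is None:
        weights = default_weights()
    profiles = [_as_profile(n) for n in networks]
    D = distance_matrix(profiles, weights=weights)
    np.fill_diagonal(D, 0.0)
    return StateSpace(profiles=profiles, weights=weights, D=D)


def calibrate_weights(calibration_networks, rng=None,
                      provenance: Optional[dict] = None) -> StackWeights:
    """PCA-derived stacking weights from a calibration panel.

    For every pair of panel networks the 18 component distances are
    computed; each component's pair-distance vector is z-scored; the
    weights are the absolute loadings of each component on the first
    principal axis, normalized to sum 1.  Components constant across the
    panel receive weight 0.
    """
    profiles = [_as_profile(n) for n in calibration_networks]
    if len(profiles) < 3:
        raise ValueError("calibration panel must contain at least 3 networks")
    n = len(profiles)
    iu = np.triu_indices(n, k=1)
    X = np.empty((len(iu[0]), len(COMPONENT_NAMES)))
    for k, c in enumerate(COMPONENT_NAMES):
        L = max(len(np.atleast_1d(p[c])) for p in profiles)
        M = _component_matrix(profiles, c, L)
        X[:, k] = cdist(M, M)[iu]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = np.zeros_like(X)
    Z[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]
    cov = np.cov(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    pc1 = np.abs(eigvecs[:, -1])
    pc1[~keep] = 0.0
    w = pc1 / pc1.sum()
    prov = {"panel_size": n, "explained_variance": float(eigvals[-1] / eigvals.sum())}
    prov.update(provenance or {})
    return StackWeights(w, prov)


def calibration_panel(n_networks: int = 300, n_nodes: int = 20, seed=0) -> list:
    """A systematic panel across all five mechanisms and both orientations.

    Each valid mechanism-orientation combination receives an equal share of
    the panel, with its governing parameter swept evenly across its range.
    """
    # every mechanism has a directed form (DD/SW by the reciprocal-arc
    # convention); only NM lacks an undirected form
    combos = [(m, d) for m in mech.MECHANISMS
              for d in (True, False) if d or m != "NM"]
    rng = np.random.default_rng(seed)
    per = [n_networks // len(combos)] * len(combos)
    for i in range(n_networks - sum(per)):
        per[i] += 1
    nets = []
    for (m, directed), count in zip(combos, per):
        lo, hi = mech.DEFAULT_PARAMETER_RANGES[m]
        for v in np.linspace(lo, hi, count):
            spec = mech.MechanismSpec(m, float(v), directed=directed)
            nets.append(mech.simulate_mechanism(spec, n_nodes, rng))
    return nets


def calibrate_default_weights(seed: int = 0, n_networks: int = 300,
                              n_nodes: int = 20) -> StackWeights:
    """Recompute the shipped default stacking weights from scratch."""
    panel = calibration_panel(n_networks, n_nodes, seed)
    return calibrate_weights(panel, provenance={
        "kind": "default", "seed": seed, "n_networks": n_networks,
        "n_nodes": n_nodes})


_DEFAULT_WEIGHTS: Optional[StackWeights] = None


def default_weights() -> StackWeights:
    """The package's shipped stacking weights (calibrated once on a seeded
    systematic 300-network panel; see :func:`calibrate_default_weights`)."""
    global _DEFAULT_WEIGHTS
    if _DEFAULT_WEIGHTS is None:
        ref = resources.files("mechnet").joinpath("data/default_weights.json")
        with resources.as_file(ref) as path:
            _DEFAULT_WEIGHTS = StackWeights.load(path)
    return _DEFAULT_WEIGHTS


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    idx = np.argsort(eigvals)[::-1][:dims]
    vals = np.clip(eigvals[idx], 0.0, None)
    return eigvecs[:, idx] * np.sqrt(vals)


def ordinate(space: StateSpace, dims: int = 2, seed=0):
    """Nonmetric multidimensional scaling of the state space.

    Initialized from the classical (metric) MDS solution, then refined by
    nonmetric stress majorization.  Returns ``(coordinates, stress)`` with
    normalized stress (Kruskal stress-1).
    """
    from sklearn.manifold import MDS

    D = np.asarray(space.D, dtype=float)
    if np.all(D == 0):
        raise ValueError("degenerate state space: all distances are zero")
    init = _classical_mds(D, dims)
    model = MDS(n_components=dims, metric_mds=False, metric="precomputed",
                n_init=1, init="classical_mds",
                random_state=np.random.default_rng(seed).integers(2 ** 31 - 1),
                normalized_stress=True, max_iter=300)
    coords = model.fit_transform(D, init=init)
    return coords, float(model.stress_)
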