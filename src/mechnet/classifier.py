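"""Monte-Carlo mechanism classification.

For each candidate mechanism the classifier (i) grid-searches the
mechanism's governing parameter for the value whose simulated networks are
on average closest to the target in the stacked-property state space, and
(ii) tests the target against a null cloud simulated at that best-fit
parameter: the p-value is the fraction of null networks whose average
distance to the other nulls exceeds the target's average distance to the
nulls.  A small p-value means the target sits outside the cloud of networks
that mechanism typically produces, so the mechanism is rejected.

Candidates are tested independently; the per-mechanism p-values are not
normalized across mechanisms, so a network can be consistent with several
mechanisms or with none of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import Network
from .mechanisms import (DEFAULT_PARAMETER_RANGES, MECHANISMS, MechanismSpec,
                         simulate_mechanism)
from .properties import property_profile
from .state_space import StackWeights, default_weights, distance_matrix

DEFAULT_GRID_SIZE = 100
DEFAULT_REPS = 50
DEFAULT_N_NULL = 500
DEFAULT_ALPHA = 0.05
_EPS = 1e-9  # inverse-distance weighting guard


class DirectednessMismatch(UserWarning):
    """A mechanism has no form matching the target's directedness."""


@dataclass
class MechanismTestResult:
    mechanism: str
    best_parameter: float
    p_value: float
    null_mean_distances: np.ndarray
    target_mean_distance: float
    verdict: bool  # True: cannot reject the mechanism at alpha


@dataclass
class ClassificationResult:
    per_mechanism: dict  # mechanism id -> MechanismTestResult
    alpha: float
    config: dict = field(default_factory=dict)

    @property
    def mechanisms_passed(self) -> set:
        return {m for m, r in self.per_mechanism.items() if r.verdict}

    @property
    def estimated_parameters(self) -> dict:
        return {m: r.best_parameter for m, r in self.per_mechanism.items()}


def _matched_spec(mechanism, target: Network) -> MechanismSpec:
    """The mechanism spec with directedness matched to the target.

    NM has no undirected form; an undirected target cannot be tested
    against it (signalled with :class:`DirectednessMismatch`).
    """
    if isinstance(mechanism, MechanismSpec):
        spec = mechanism
    else:
        if mechanism not in DEFAULT_PARAMETER_RANGES:
            raise ValueError(f"unknown mechanism {mechanism!r}")
        lo, _ = DEFAULT_PARAMETER_RANGES[mechanism]
        spec = MechanismSpec(mechanism, lo, directed=True)
    if spec.mechanism == "NM" and not target.directed:
        raise DirectednessMismatch(
            "the niche model is directed-only; undirected target skipped")
    return MechanismSpec(spec.mechanism, spec.parameter, directed=target.directed,
                         parameter_range=spec.parameter_range,
                         secondary=dict(spec.secondary))


def best_fit_parameter(target: Network, mechanism, grid_size: int = DEFAULT_GRID_SIZE,
                       reps: int = DEFAULT_REPS,
                       weights: Optional[StackWeights] = None, rng=None) -> float:
    """Grid search for the parameter whose networks most resemble the target.

    Evaluates ``grid_size`` evenly spaced values over the mechanism's
    admissible range, simulating ``reps`` networks per value with the
    target's node count and directedness; returns the value minimizing the
    mean stacked distance to the target (ties break toward the smaller
    value).
    """
    if target.n_nodes < 3:
        raise ValueError("target must have at least 3 nodes")
    if grid_size < 1 or reps < 1:
        raise ValueError("grid_size and reps must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if weights is None:
        weights = default_weights()
    spec = _matched_spec(mechanism, target)
    lo, hi = spec.parameter_range
    grid = np.linspace(lo, hi, grid_size) if grid_size > 1 else np.array([lo])
    target_profile = property_profile(target)
    mean_dist = np.empty(len(grid))
    for g, value in enumerate(grid):
        sims = [simulate_mechanism(spec.with_parameter(float(value)), target.n_nodes, rng)
                for _ in range(reps)]
        d = distance_matrix([target_profile], [property_profile(s) for s in sims],
                            weights=weights)
        mean_dist[g] = d.mean()
    return float(grid[int(np.argmin(mean_dist))])  # argmin -> first (smallest) on ties


def mechanism_test(target: Network, mechanism, best_param: float,
                   n_null: int = DEFAULT_N_NULL,
                   weights: Optional[StackWeights] = None, rng=None):
    """Monte-Carlo test of the target against one mechanism at one parameter.

    Simulates ``n_null`` networks at ``best_param``; each null's score is
    its mean distance to the other nulls (the target is excluded from the
    null cloud's internal averages), the target's score is its mean
    distance to all nulls.  ``p`` is the fraction of null scores larger
    than the target's score, with exact ties counted as larger (ties have
    probability zero for non-degenerate clouds; counting them up keeps the
    test conservative toward non-rejection, e.g. a target identical to a
    cloud of identical nulls is never rejected).

    Returns ``(p_value, null_mean_distances, target_mean_distance)``.
    """
    if n_null < 2:
        raise ValueError("n_null must be at least 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if weights is None:
        weights = default_weights()
    spec = _matched_spec(mechanism, target)
    nulls = [simulate_mechanism(spec.with_parameter(float(best_param)),
                                target.n_nodes, rng) for _ in range(n_null)]
    null_profiles = [property_profile(s) for s in nulls]
    D = distance_matrix(null_profiles, weights=weights)
    np.fill_diagonal(D, 0.0)
    null_means = D.sum(axis=1) / (n_null - 1)
    t = distance_matrix([property_profile(target)], null_profiles, weights=weights)
    target_mean = float(t.mean())
    p_value = float(np.mean(null_means >= target_mean))
    return p_value, null_means, target_mean


def classify(target: Network, candidate_mechanisms: Sequence,
             alpha: float = DEFAULT_ALPHA, grid_size: int = DEFAULT_GRID_SIZE,
             reps: int = DEFAULT_REPS, n_null: int = DEFAULT_N_NULL,
             weights: Optional[StackWeights] = None, rng=None,
             seed: Optional[int] = None) -> ClassificationResult:
    """Test the target against each candidate mechanism independently.

    Per mechanism: grid-search the best-fit parameter, then run the
    Monte-Carlo null test at that parameter.  Verdict ``True`` (cannot
    reject) iff ``p >= alpha``.  Mechanisms without a form matching the
    target's directedness are skipped with a warning.
    """
    if len(candidate_mechanisms) == 0:
        raise ValueError("need at least one candidate mechanism")
    if target.n_nodes < 3:
        raise ValueError("target must have at least 3 nodes")
    if weights is None:
        weights = default_weights()
    master = np.random.default_rng(seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    # independent substream per mechanism, keyed by the mechanism's fixed
    # index: adding or removing another candidate never shifts this one's
    # draws, so its p-value is unchanged
    base_entropy = int(master.integers(2 ** 31 - 1))
    results = {}
    for mechanism in candidate_mechanisms:
        name = mechanism.mechanism if isinstance(mechanism, MechanismSpec) else mechanism
        key = MECHANISMS.index(name) if name in MECHANISMS else len(MECHANISMS)
        sub = np.random.default_rng(np.random.SeedSequence(base_entropy, spawn_key=(key,)))
        try:
            best = best_fit_parameter(target, mechanism, grid_size, reps, weights, sub)
        except DirectednessMismatch as exc:
            warnings.warn(str(exc), DirectednessMismatch)
            continue
        p, null_means, target_mean = mechanism_test(
            target, mechanism, best, n_null, weights, sub)
        results[name] = MechanismTestResult(
            mechanism=name, best_parameter=best, p_value=p,
            null_mean_distances=null_means, target_mean_distance=target_mean,
            verdict=p >= alpha)
    return ClassificationResult(per_mechanism=results, alpha=alpha, config={
        "grid_size": grid_size, "reps": reps, "n_null": n_null,
        "alpha": alpha, "seed": seed})


def estimate_parameter(target: Network, panel_parameters: Sequence[float],
                       panel_networks: Sequence,
                       weights: Optional[StackWeights] = None,
                       eps: float = _EPS) -> float:
    """Inverse-distance-weighted average of known panel parameters.

    ``w_i = 1 / (d_i + eps)``; a panel member at (numerically) zero
    distance short-circuits to its own parameter.
    """
    if len(panel_parameters) == 0 or len(panel_parameters) != len(panel_networks):
        raise ValueError("panel parameters and networks must align and be nonempty")
    if weights is None:
        weights = default_weights()
    d = distance_matrix([target], panel_networks, weights=weights)[0]
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite panel distance")
    params = np.asarray(panel_parameters, dtype=float)
    if np.any(d < eps):
        return float(params[int(np.argmin(d))])
    w = 1.0 / (d + eps)
    return float((w * params).sum() / w.sum())
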