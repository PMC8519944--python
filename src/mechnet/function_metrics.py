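"""Whole-system function: Ascendency and its out-of-sample prediction.

Ascendency is a thermodynamic index of ecosystem growth and development.
Treating the adjacency as a flow matrix T (binary networks become
unit-flow matrices), with T.. the total system throughput:

    A = sum_ij T_ij * log( T_ij * T.. / (T_i. * T_.j) )   (ascendency)
    C = -sum_ij T_ij * log( T_ij / T.. )                  (development capacity)

A is total flow times the average mutual information of the flow
distribution; C bounds it from above, so normalized ascendency A/C lies in
[0, 1].  A/C = 1 for perfectly determinate (permutation-structured) flows
and 0 when flows carry no information about their destination.

Normalized ascendency is a *functional* property, deliberately outside the
structural classification ensemble, which makes it an out-of-sample check:
networks nearby in the state space should function similarly, so A/C can
be predicted from state-space neighbours by leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .network import Network
from .state_space import StateSpace, build_state_space

_EPS = 1e-9


@dataclass
class AscendencyResult:
    ascendency: float
    capacity: float
    normalized: Optional[float]  # None when capacity is 0 (undefined)

    @property
    def defined(self) -> bool:
        return self.normalized is not None


def ascendency(net) -> AscendencyResult:
    """Ascendency A, development capacity C and normalized A/C of a flow
    network (sums run over positive entries only; natural log)."""
    T = net.adjacency if isinstance(net, Network) else np.asarray(net, dtype=float)
    if np.any(T < 0):
        raise ValueError("flow matrix must be nonnegative")
    total = T.sum()
    if total == 0:
        return AscendencyResult(0.0, 0.0, None)
    row = T.sum(axis=1)
    col = T.sum(axis=0)
    i, j = np.nonzero(T)
    t = T[i, j]
    A = float((t * np.log(t * total / (row[i] * col[j]))).sum())
    C = float(-(t * np.log(t / total)).sum())
    normalized = A / C if C > 0 else None
    return AscendencyResult(A, C, normalized)


def predict_function_loocv(networks: Sequence, space: Optional[StateSpace] = None,
                           weights=None, k: Optional[int] = None):
    """Leave-one-out prediction of normalized ascendency from the state space.

    Each network's A/C is predicted as the inverse-distance-weighted mean of
    every other panel member's A/C (``w_j = 1/(d_j + eps)``, the same
    weighting contract as parameter estimation); with ``k`` set, only the k
    nearest neighbours contribute.  Returns ``(predictions, actual, r2)``;
    ``r2`` is None when the panel's A/C has zero variance.
    """
    if len(networks) < 5:
        raise ValueError("panel must contain at least 5 networks")
    if space is None:
        space = build_state_space(networks, weights=weights)
    D = np.asarray(space.D, dtype=float)
    y = np.array([_normalized_or_zero(n) for n in networks])
    n = len(networks)
    preds = np.empty(n)
    for i in range(n):
        d = np.delete(D[i], i)
        vals = np.delete(y, i)
        if k is not None:
            idx = np.argsort(d)[:k]
            d, vals = d[idx], vals[idx]
        w = 1.0 / (d + _EPS)
        preds[i] = (w * vals).sum() / w.sum()
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return preds, y, None
    ss_res = float(((y - preds) ** 2).sum())
    return preds, y, 1.0 - ss_res / ss_tot


def _normalized_or_zero(net) -> float:
    r = ascendency(net)
    if r.normalized is None:
        raise ValueError("a panel network has undefined normalized ascendency")
    return r.normalized
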