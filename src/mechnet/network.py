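"""Core network container.

Every module in this package exchanges networks as a square nonnegative
adjacency matrix with an explicit directedness flag.  Mechanism simulators
emit binary (0/1) adjacencies; the Markov transform produces weighted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Network:
    """A (possibly weighted) graph stored as a dense adjacency matrix.

    Parameters
    ----------
    adjacency:
        Square ``(n, n)`` array of nonnegative weights.  ``adjacency[i, j] > 0``
        means an edge (arc, if directed) from node ``i`` to node ``j``.
    directed:
        If False the adjacency must be symmetric and each undirected edge is
        stored in both triangles.
    node_ids:
        Ordered node labels; defaults to ``0 .. n-1``.
    """

    adjacency: np.ndarray
    directed: bool = False
    node_ids: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.adjacency.ndim != 2 or self.adjacency.shape[0] != self.adjacency.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if np.any(self.adjacency < 0):
            raise ValueError("adjacency weights must be nonnegative")
        # NOTE: mechanism simulators always emit a zero diagonal; the Markov
        # transform legitimately carries self-transition mass, so the type
        # itself does not forbid diagonal entries.
        if not self.directed and not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("undirected network requires a symmetric adjacency")
        if self.node_ids is None:
            self.node_ids = list(range(self.adjacency.shape[0]))
        elif len(self.node_ids) != self.adjacency.shape[0]:
            raise ValueError("node_ids length must equal the number of nodes")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Edge count: arcs if directed, unordered pairs if undirected."""
        m = int(np.count_nonzero(self.adjacency))
        return m if self.directed else m // 2

    def is_binary(self) -> bool:
        a = self.adjacency
        return bool(np.all((a == 0) | (a == 1)))

    def copy(self) -> "Network":
        return Network(self.adjacency.copy(), self.directed, list(self.node_ids))

    def symmetrized(self) -> "Network":
        """Undirected view: keep an edge wherever either arc exists (max weight)."""
        return Network(np.maximum(self.adjacency, self.adjacency.T), directed=False,
                       node_ids=list(self.node_ids))

    def relabeled(self, permutation: np.ndarray) -> "Network":
        """Apply a node permutation: node ``i`` becomes ``permutation[i]``."""
        perm = np.asarray(permutation)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        a = self.adjacency[np.ix_(inv, inv)]
        return Network(a, self.directed, [self.node_ids[i] for i in inv])
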