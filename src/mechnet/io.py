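"""Network readers/writers, run configuration and fixture generation.

Supported formats: two-column (optionally weighted) edge-list TSV with
``#`` comments, adjacency-matrix CSV, and GraphML.  Node ids are compacted
to ``0..n-1`` on read (the original labels are preserved on the returned
network); self-loops are dropped with a warning and duplicate edges are
collapsed.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import yaml

from .network import Network
from . import mechanisms as mech
from .mixtures import random_mixture

log = logging.getLogger("mechnet")

FORMATS = ("edgelist", "adjacency", "graphml")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".graphml":
        return "graphml"
    if suffix == ".csv":
        return "adjacency"
    return "edgelist"


def read_network(path, fmt: Optional[str] = None,
                 directed: Optional[bool] = None) -> Network:
    """Read a network from disk.

    ``directed=None`` infers directedness: an asymmetric adjacency is
    directed, a symmetric one undirected.  Forcing ``directed=False`` on
    asymmetric content symmetrizes with the elementwise maximum.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "edgelist":
        a, labels = _read_edgelist(path)
    elif fmt == "adjacency":
        a = np.loadtxt(path, delimiter=",", ndmin=2)
        if a.shape[0] != a.shape[1]:
            raise ValueError(f"{path}: adjacency matrix is not square")
        labels = list(range(a.shape[0]))
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        labels = list(g.nodes())
        a = nx.to_numpy_array(g, nodelist=labels)
        if directed is None:
            directed = g.is_directed()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if np.any(np.diag(a) != 0):
        warnings.warn(f"{path}: dropped {int(np.count_nonzero(np.diag(a)))} self-loop(s)")
        np.fill_diagonal(a, 0.0)
    symmetric = np.array_equal(a, a.T)
    if directed is None:
        directed = not symmetric
    if not directed and not symmetric:
        warnings.warn(f"{path}: asymmetric content declared undirected; "
                      "symmetrizing with the elementwise maximum")
        a = np.maximum(a, a.T)
    return Network(a, directed=directed, node_ids=labels)


def _read_edgelist(path: Path):
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, "
                                 f"got {len(parts)}")
            weight = 1.0
            if len(parts) == 3:
                try:
                    weight = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            edges.append((parts[0], parts[1], weight))
    labels = sorted({u for u, v, _ in edges} | {v for u, v, _ in edges},
                    key=_label_key)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    a = np.zeros((n, n))
    for u, v, w in edges:
        a[index[u], index[v]] = w  # duplicates collapse to the last weight
    return a, labels


def _label_key(label: str):
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


def write_network(net: Network, path, fmt: Optional[str] = None) -> None:
    """Write a network: edge-list TSV (0-based ids), adjacency CSV, or
    GraphML by extension."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            a = net.adjacency
            weighted = not net.is_binary()
            # every arc is listed (undirected edges appear in both
            # directions) so that symmetry survives the round trip and
            # directedness can be re-inferred on read
            rows, cols = np.nonzero(a)
            for i, j in zip(rows, cols):
                if weighted:
                    fh.write(f"{i}\t{j}\t{a[i, j]:.12g}\n")
                else:
                    fh.write(f"{i}\t{j}\n")
    elif fmt == "adjacency":
        np.savetxt(path, net.adjacency, delimiter=",", fmt="%.12g")
    elif fmt == "graphml":
        g = _to_networkx(net)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _to_networkx(net: Network):
    cls = nx.DiGraph if net.directed else nx.Graph
    g = cls()
    g.add_nodes_from(range(net.n_nodes))
    a = net.adjacency if net.directed else np.triu(net.adjacency)
    for i, j in zip(*np.nonzero(a)):
        g.add_edge(int(i), int(j), weight=float(net.adjacency[i, j]))
    return g


@dataclass
class RunConfig:
    """Serializable configuration echoed into every result file."""

    mechanisms: tuple = mech.MECHANISMS
    parameter_ranges: dict = field(
        default_factory=lambda: dict(mech.DEFAULT_PARAMETER_RANGES))
    grid_size: int = 100
    reps: int = 50
    n_null: int = 500
    alpha: float = 0.05
    n_nodes: int = 20
    seed: Optional[int] = None
    weights_path: Optional[str] = None

    def __post_init__(self):
        for name in ("grid_size", "reps", "n_null", "n_nodes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mechanisms"] = list(self.mechanisms)
        d["parameter_ranges"] = {m: list(r) for m, r in d["parameter_ranges"].items()}
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "mechanisms" in data:
            data["mechanisms"] = tuple(data["mechanisms"])
        return cls(**data)


def generate_fixtures(out_dir, rng=None, n_nodes: int = 20,
                      params_per_mechanism: int = 3, replicates: int = 5,
                      n_mixtures: int = 20):
    """Write a seeded labelled corpus of simulated networks.

    Per mechanism x orientation x ``params_per_mechanism`` evenly spaced
    parameter values x ``replicates`` at ``n_nodes`` nodes, plus
    ``n_mixtures`` random five-mechanism mixtures with ground-truth sidecar
    JSONs; a manifest CSV indexes everything.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for m in mech.MECHANISMS:
        for directed in (True, False):
            if m == "NM" and not directed:
                continue
            lo, hi = mech.DEFAULT_PARAMETER_RANGES[m]
            for v in np.linspace(lo, hi, params_per_mechanism):
                for rep in range(replicates):
                    seed = int(rng.integers(2 ** 31 - 1))
                    spec = mech.MechanismSpec(m, float(v), directed=directed)
                    net = mech.simulate_mechanism(spec, n_nodes,
                                                  np.random.default_rng(seed))
                    orient = "dir" if directed else "und"
                    name = f"{m}_{orient}_p{v:.3f}_r{rep}.tsv"
                    write_network(net, out_dir / name)
                    manifest.append({"file": name, "kind": "pure", "mechanism": m,
                                     "directed": directed, "parameter": round(v, 6),
                                     "seed": seed})
    for i in range(n_mixtures):
        spec, net = random_mixture(n_nodes, rng=rng)
        name = f"mixture_{i:02d}.tsv"
        write_network(net, out_dir / name)
        sidecar = {"assignments": list(spec.assignments),
                   "parameters": [float(p) for p in spec.parameters],
                   "seed": spec.seed, "process": spec.process}
        with open(out_dir / f"mixture_{i:02d}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        manifest.append({"file": name, "kind": "mixture", "mechanism": "mixture",
                         "directed": True, "parameter": "", "seed": spec.seed})
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["file", "kind", "mechanism",
                                                "directed", "parameter", "seed"])
        writer.writeheader()
        writer.writerows(manifest)
    log.info("wrote %d fixtures to %s", len(manifest), out_dir)
    return manifest
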