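"""Domain interaction network and graph-proximity kernels.

The network is an undirected simple graph over protein domains. Two
proximity measures are derived from it:

* the diffusion kernel ``K = exp(-gamma * L)`` with ``L = D - A`` the graph
  Laplacian, a global measure in which proximity between two nodes reflects
  all paths connecting them; and
* the shortest-path Gaussian kernel ``SG(u, v) = exp(-beta * SP(u, v)**2)``,
  a local measure driven only by hop distance.

Both yield a symmetric nonnegative matrix indexed by a fixed node order
(sorted domain identifiers), so repeated runs are bit-for-bit reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "DomainNetwork",
    "KernelParams",
    "ProximityMatrix",
    "build_laplacian",
    "diffusion_kernel",
    "shortest_path_lengths",
    "sg_kernel",
    "degree_preserving_shuffle",
]


@dataclass(frozen=True)
class KernelParams:
    """Free parameters of the two proximity measures.

    beta
        Bandwidth of the shortest-path Gaussian kernel; must be > 0.
        Default 1.
    gamma
        Diffusion magnitude of the diffusion kernel; nominally in (0, 1).
        Default 0.05.
    """

    beta: float = 1.0
    gamma: float = 0.05

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("invalid bandwidth: beta must be > 0")
        if not 0 < self.gamma < 1:
            warnings.warn(
                f"gamma={self.gamma} outside (0, 1); allowed for robustness sweeps",
                stacklevel=2,
            )


class DomainNetwork:
    """Undirected simple graph of protein domains with a fixed node order.

    Nodes are string identifiers; the canonical order is the sorted order of
    identifiers, fixed at construction, and indexes every derived matrix.
    Self-loops in the input are dropped with a warning; duplicate and
    reversed-duplicate edges are merged.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]):
        node_ids = sorted(set(str(n) for n in nodes))
        node_set = set(node_ids)
        edge_set: set[tuple[str, str]] = set()
        n_loops = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                n_loops += 1
                continue
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not in node list: ({u}, {v})")
            edge_set.add((u, v) if u < v else (v, u))
        if n_loops:
            warnings.warn(f"dropped {n_loops} self-loop(s)", stacklevel=2)
        self.node_ids: list[str] = node_ids
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)
        self._index = {d: i for i, d in enumerate(node_ids)}

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "DomainNetwork":
        edges = list(edges)
        nodes = {u for e in edges for u in e}
        return cls(nodes, edges)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, domain: str) -> int:
        return self._index[domain]

    def __contains__(self, domain: str) -> bool:
        return domain in self._index

    def degree_sequence(self) -> list[int]:
        """Degrees in canonical node order."""
        deg = dict.fromkeys(self.node_ids, 0)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return [deg[d] for d in self.node_ids]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n, self.n), dtype=np.int64)
        for u, v in self.edges:
            i, j = self._index[u], self._index[v]
            a[i, j] = a[j, i] = 1
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g


@dataclass
class ProximityMatrix:
    """Symmetric nonnegative domain-proximity matrix over a fixed node order.

    ``kind`` tags the measure: ``"DK"`` (diffusion kernel) or ``"SG"``
    (shortest-path Gaussian).
    """

    node_ids: Sequence[str]
    values: np.ndarray
    kind: str
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError("proximity matrix shape does not match node list")
        self._index = {d: i for i, d in enumerate(self.node_ids)}

    def index_of(self, domain: str) -> int:
        return self._index[domain]

    def __contains__(self, domain: str) -> bool:
        return domain in self._index


def _require_nonempty(net: DomainNetwork) -> None:
    if net.n == 0:
        raise ValueError("empty network")


def build_laplacian(net: DomainNetwork) -> np.ndarray:
    """Graph Laplacian L = D - A in canonical node order."""
    _require_nonempty(net)
    a = net.adjacency()
    return np.diag(a.sum(axis=1)) - a


def diffusion_kernel(net: DomainNetwork, gamma: float = 0.05) -> ProximityMatrix:
    """Diffusion kernel K = exp(-gamma * L).

    Computed by symmetric eigendecomposition of L (exact for symmetric
    matrices), so K is symmetric PSD by construction; its rows sum to one
    because L annihilates the constant vector.
    """
    _require_nonempty(net)
    if not 0 < gamma < 1:
        warnings.warn(
            f"gamma={gamma} outside (0, 1); allowed for robustness sweeps",
            stacklevel=2,
        )
    lap = build_laplacian(net).astype(float)
    eigval, eigvec = np.linalg.eigh(lap)
    k = (eigvec * np.exp(-gamma * eigval)) @ eigvec.T
    if not np.all(np.isfinite(k)):
        raise FloatingPointError("kernel computation failed")
    k = np.maximum((k + k.T) / 2.0, 0.0)  # clip eigh round-off below zero
    return ProximityMatrix(net.node_ids, k, "DK")


def shortest_path_lengths(net: DomainNetwork) -> np.ndarray:
    """All-pairs shortest-path hop counts; ``inf`` for disconnected pairs."""
    _require_nonempty(net)
    n = net.n
    sp = np.full((n, n), np.inf)
    np.fill_diagonal(sp, 0.0)
    g = net.to_networkx()
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        i = net.index_of(src)
        for dst, dist in lengths.items():
            sp[i, net.index_of(dst)] = dist
    return sp


def sg_kernel(net: DomainNetwork, beta: float = 1.0) -> ProximityMatrix:
    """Shortest-path Gaussian kernel SG(u, v) = exp(-beta * SP(u, v)**2).

    Disconnected pairs (SP = inf) map to 0, the limit of the formula; the
    diagonal is exactly 1.
    """
    if not beta > 0:
        raise ValueError("invalid bandwidth: beta must be > 0")
    sp = shortest_path_lengths(net)
    with np.errstate(over="ignore"):
        sg = np.exp(-beta * sp**2)
    sg[np.isinf(sp)] = 0.0
    return ProximityMatrix(net.node_ids, sg, "SG")


def degree_preserving_shuffle(
    net: DomainNetwork, seed: int, n_swaps: int | None = None
) -> DomainNetwork:
    """Randomize edges by double-edge swaps, preserving every node degree.

    ``n_swaps`` defaults to 10 x |E| attempted swaps, a standard mixing
    heuristic. If the graph admits no valid swap the input is returned
    unchanged with a warning.
    """
    if net.n_edges < 2:
        warnings.warn("network has < 2 edges; no swap possible", stacklevel=2)
        return net
    if n_swaps is None:
        n_swaps = 10 * net.n_edges
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    g = net.to_networkx()
    try:
        nx.double_edge_swap(
            g, nswap=n_swaps, max_tries=100 * n_swaps, seed=int(seed)
        )
    except nx.NetworkXError as exc:
        warnings.warn(f"degree-preserving shuffle failed ({exc}); "
                      "returning network unchanged", stacklevel=2)
        return net
    except nx.NetworkXAlgorithmError:
        # max_tries exhausted: keep whatever mixing was achieved
        pass
    return DomainNetwork(net.node_ids, g.edges())
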