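"""Nodal efficiency measures and weight-to-length conversion.

Clustering coefficient (CC) quantifies the fraction of closed triangles
around a node; local efficiency (LE) the mean inverse shortest-path
length among its neighbours inside the neighbour-induced subgraph.  Both
come in a binary and a weighted variant; the weighted CC is the Onnela
geometric-mean form over max-normalized weights, and the weighted LE
runs shortest paths on reciprocal lengths within the neighbour subgraph.

Lengths: streamline counts are similarities, so routing and geodesics
operate on a weight-to-length transform (reciprocal by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .netcore import WeightedConnectome

DEFAULT_MODE = "weighted"
DEFAULT_LENGTH_TRANSFORM = "reciprocal"
NEGLOG_EPS = 1e-3


@dataclass(frozen=True)
class NodalMetrics:
    node: str
    cc: float
    le: float
    degree: int
    strength: float


@dataclass(frozen=True)
class LengthMatrix:
    """Edge lengths d_ij; ``inf`` off edges, diagonal 0 by convention."""

    lengths: np.ndarray
    transform_name: str
    node_labels: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return self.lengths.shape[0]

    def adjacency(self) -> np.ndarray:
        """Boolean edge-existence mask (off-diagonal finite lengths)."""
        m = np.isfinite(self.lengths)
        np.fill_diagonal(m, False)
        return m


@dataclass(frozen=True)
class GeodesicMatrix:
    """All-pairs shortest-path lengths g over a LengthMatrix."""

    g: np.ndarray
    node_labels: tuple[str, ...]


def _as_graph(c: WeightedConnectome) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(c.n_nodes))
    iu, ju = np.nonzero(np.triu(c.weights, k=1))
    g.add_weighted_edges_from(
        (int(i), int(j), float(c.weights[i, j])) for i, j in zip(iu, ju)
    )
    return g


def clustering_coefficient(
    c: WeightedConnectome, node: str, mode: str = DEFAULT_MODE
) -> float:
    """Clustering coefficient of ``node``.

    Binary: 2·(closed triangles)/(k(k−1)); weighted: Onnela
    geometric-mean triangle intensity with weights max-normalized, which
    reduces to the binary value on uniform weights.  0 when degree < 2.
    """
    i = c.index_of(node)
    g = _as_graph(c)
    if g.degree(i) < 2:
        return 0.0
    if mode == "binary":
        return float(nx.clustering(g, i))
    if mode == "weighted":
        return float(nx.clustering(g, i, weight="weight"))
    raise ValueError(f"unknown mode {mode!r}")


def local_efficiency(
    c: WeightedConnectome, node: str, mode: str = DEFAULT_MODE
) -> float:
    """Local efficiency of ``node``.

    Mean of 1/shortest-path-length over all ordered neighbour pairs,
    paths confined to the subgraph induced by the neighbours (the node
    itself is excluded, so it cannot serve as a 2-step detour).  In
    weighted mode path lengths use reciprocal max-normalized weights so
    that a uniform-weight graph reproduces the binary value.  0 when
    degree < 2.
    """
    i = c.index_of(node)
    w = c.weights
    nbrs = np.flatnonzero(w[i] > 0)
    k = nbrs.size
    if k < 2:
        return 0.0
    sub = w[np.ix_(nbrs, nbrs)]
    if mode == "binary":
        lengths = np.where(sub > 0, 1.0, np.inf)
    elif mode == "weighted":
        wmax = w[w > 0].max()
        lengths = np.where(sub > 0, wmax / np.where(sub > 0, sub, 1.0), np.inf)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(lengths, 0.0)
    sp = dijkstra(csr_array(np.where(np.isfinite(lengths), lengths, 0.0)),
                  directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (k * (k - 1)))


def nodal_metrics(
    c: WeightedConnectome, node: str, mode: str = DEFAULT_MODE
) -> NodalMetrics:
    i = c.index_of(node)
    return NodalMetrics(
        node=node,
        cc=clustering_coefficient(c, node, mode),
        le=local_efficiency(c, node, mode),
        degree=int(c.degree()[i]),
        strength=float(c.strength()[i]),
    )


def weight_to_length(
    c: WeightedConnectome,
    transform: str = DEFAULT_LENGTH_TRANSFORM,
    eps: float = NEGLOG_EPS,
) -> LengthMatrix:
    """Convert streamline counts to edge lengths.

    ``reciprocal``: d = 1/w.  ``neglog``: d = −log(w / max w) + eps with
    eps > 0 so the strongest edge keeps a positive length.  Off-edge
    entries are infinite; both transforms are strictly decreasing in w.
    """
    w = c.weights
    on = w > 0
    if np.any(w[on] <= 0):  # pragma: no cover - guarded by on-mask
        raise ValueError("nonpositive weight on an existing edge")
    d = np.full_like(w, np.inf, dtype=float)
    if transform == "reciprocal":
        d[on] = 1.0 / w[on]
    elif transform == "neglog":
        if eps <= 0:
            raise ValueError("neglog eps must be > 0")
        d[on] = -np.log(w[on] / w[on].max()) + eps
    else:
        raise ValueError(f"unknown transform {transform!r}")
    np.fill_diagonal(d, 0.0)
    return LengthMatrix(d, transform, c.node_labels)


def geodesic_matrix(d: LengthMatrix) -> GeodesicMatrix:
    """Exact all-pairs shortest paths (Dijkstra); inf where unreachable."""
    lengths = d.lengths
    off = lengths[d.adjacency()]
    if off.size and np.any(off < 0):
        raise ValueError("negative edge length")
    graph = np.where(np.isfinite(lengths), lengths, 0.0)
    np.fill_diagonal(graph, 0.0)
    g = dijkstra(csr_array(graph), directed=False)
    return GeodesicMatrix(g, d.node_labels)
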