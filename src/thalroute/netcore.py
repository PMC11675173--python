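"""Connectome data model, I/O, thresholding, hubs and subnetworks.

Nodes are gray-matter parcels (by default the 90-region AAL labelling);
edges are streamline counts from deterministic tractography, stored as a
dense symmetric nonnegative matrix with zero diagonal.  An optional
parallel matrix carries mean fractional anisotropy (FA) per edge, used
downstream only as a statistical covariate, never for edge existence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Streamline-count threshold: edges carried by fewer streamlines are
#: treated as false-positive tracts and removed.
DEFAULT_STREAMLINE_THRESHOLD = 3

#: Degree cut-off for hub status (strict: a hub has MORE than this many
#: directly connected neighbours).
DEFAULT_HUB_DEGREE_THRESHOLD = 20

#: Canonical left-thalamus label in the packaged AAL ordering.
LEFT_THALAMUS = "Thalamus_L"

_SYMMETRY_RTOL = 1e-8


class ConnectomeError(ValueError):
    """Raised for malformed connectome inputs."""


# ---------------------------------------------------------------------------
# Packaged region fixtures
# ---------------------------------------------------------------------------

def _read_packaged_labels(name: str) -> list[str]:
    text = resources.files("thalroute.data").joinpath(name).read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


def aal90_labels() -> list[str]:
    """The packaged 90-region AAL label ordering."""
    return _read_packaged_labels("aal90_labels.txt")


def reading_network_labels(hemisphere: str = "left") -> list[str]:
    """The 13-region reading-network label list (incl. the thalamus)."""
    if hemisphere not in ("left", "right"):
        raise ValueError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
    return _read_packaged_labels(f"reading_network_{hemisphere}.txt")


def load_region_list(path: str | Path) -> list[str]:
    """Read a one-label-per-line region file."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightedConnectome:
    """Labelled symmetric streamline-count matrix with optional FA.

    Parameters
    ----------
    node_labels : sequence of str
        Unique region identifiers, in matrix order.
    weights : ndarray, shape (n, n)
        Symmetric, nonnegative, zero-diagonal streamline counts.
    fa : ndarray or None
        Per-edge mean fractional anisotropy in [0, 1], sharing the
        sparsity pattern of ``weights``.
    subject_id : str
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray
    fa: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.node_labels)
        object.__setattr__(self, "node_labels", labels)
        w = np.asarray(self.weights, dtype=float)
        validate_weight_matrix(w, labels)
        object.__setattr__(self, "weights", w)
        if self.fa is not None:
            f = np.asarray(self.fa, dtype=float)
            validate_fa_matrix(f, w, labels)
            object.__setattr__(self, "fa", f)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def index_of(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise KeyError(f"node {label!r} not in connectome") from None

    def degree(self) -> np.ndarray:
        """Number of directly connected neighbours per node."""
        return (self.weights > 0).sum(axis=1)

    def strength(self) -> np.ndarray:
        """Sum of incident edge weights per node."""
        return self.weights.sum(axis=1)

    def edge_list(self) -> list[tuple[int, int]]:
        """Upper-triangle (i, j) index pairs of existing edges."""
        iu, ju = np.nonzero(np.triu(self.weights, k=1))
        return list(zip(iu.tolist(), ju.tolist()))


@dataclass(frozen=True)
class NetworkDefinition:
    """Hub set, reading-network set and the pivot (left thalamus)."""

    hub_nodes: frozenset[str]
    reading_nodes: frozenset[str]
    pivot_node: str = LEFT_THALAMUS

    def __post_init__(self) -> None:
        object.__setattr__(self, "hub_nodes", frozenset(self.hub_nodes))
        object.__setattr__(self, "reading_nodes", frozenset(self.reading_nodes))
        if self.pivot_node not in self.reading_nodes:
            raise ConnectomeError(
                f"pivot node {self.pivot_node!r} must be a reading-network node"
            )

    @property
    def subnetwork_nodes(self) -> frozenset[str]:
        return self.hub_nodes | self.reading_nodes


@dataclass(frozen=True)
class ProbabilisticIndex:
    """Normalized probabilistic-tractography connectivity index.

    ``index = log(waytotal) / log(5000 * v_seed)`` where waytotal is the
    surviving streamline count and v_seed the seed-region voxel count;
    5000 is the number of samples drawn per seed voxel.
    """

    waytotal: int
    v_seed: int
    index: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "index", normalized_connectivity_index(self.waytotal, self.v_seed)
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_weight_matrix(w: np.ndarray, labels: Sequence[str]) -> None:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConnectomeError(f"weight matrix must be square, got shape {w.shape}")
    n = w.shape[0]
    if len(labels) != n:
        raise ConnectomeError(f"{len(labels)} labels for a {n}x{n} matrix")
    if len(set(labels)) != n:
        dupes = sorted({x for x in labels if list(labels).count(x) > 1})
        raise ConnectomeError(f"duplicate node labels: {dupes}")
    if not np.all(np.isfinite(w)):
        i, j = np.argwhere(~np.isfinite(w))[0]
        raise ConnectomeError(f"non-finite weight at ({labels[i]}, {labels[j]})")
    if np.any(w < 0):
        i, j = np.argwhere(w < 0)[0]
        raise ConnectomeError(
            f"negative weight {w[i, j]} at ({labels[i]}, {labels[j]})"
        )
    asym = ~np.isclose(w, w.T, rtol=_SYMMETRY_RTOL, atol=0)
    if np.any(asym):
        i, j = np.argwhere(asym)[0]
        raise ConnectomeError(
            f"asymmetric weights: cell ({labels[j]}, {labels[i]}) = {w[j, i]} "
            f"but ({labels[i]}, {labels[j]}) = {w[i, j]}"
        )
    if np.any(np.diag(w) != 0):
        i = int(np.argwhere(np.diag(w) != 0)[0])
        raise ConnectomeError(f"nonzero diagonal at node {labels[i]}")


def validate_fa_matrix(f: np.ndarray, w: np.ndarray, labels: Sequence[str]) -> None:
    if f.shape != w.shape:
        raise ConnectomeError(
            f"FA shape {f.shape} does not match weights shape {w.shape}"
        )
    if np.any((f < 0) | (f > 1)):
        i, j = np.argwhere((f < 0) | (f > 1))[0]
        raise ConnectomeError(
            f"FA value {f[i, j]} outside [0, 1] at ({labels[i]}, {labels[j]})"
        )
    # FA must live on existing edges only
    off = (f != 0) & (w == 0)
    if np.any(off):
        i, j = np.argwhere(off)[0]
        raise ConnectomeError(
            f"FA present at ({labels[i]}, {labels[j]}) where no edge exists"
        )


# ---------------------------------------------------------------------------
# I/O — tab-separated labelled matrix, or 3-column edge list
# ---------------------------------------------------------------------------

def load_connectome(
    matrix_source: str | Path,
    fa_source: str | Path | None = None,
    subject_id: str | None = None,
) -> WeightedConnectome:
    """Load a labelled square connectivity matrix (TSV, labels in first
    row and first column), with an optional parallel FA matrix."""
    wdf = pd.read_csv(matrix_source, sep="\t", index_col=0)
    labels = [str(x) for x in wdf.index]
    if [str(x) for x in wdf.columns] != labels:
        raise ConnectomeError(
            f"row/column labels differ in {matrix_source}: "
            f"rows start {labels[:3]}, columns start {list(wdf.columns[:3])}"
        )
    fa = None
    if fa_source is not None:
        fdf = pd.read_csv(fa_source, sep="\t", index_col=0)
        if ([str(x) for x in fdf.index] != labels
                or [str(x) for x in fdf.columns] != labels):
            raise ConnectomeError(
                f"FA labels in {fa_source} do not match weight labels"
            )
        fa = fdf.to_numpy(dtype=float)
    if subject_id is None:
        subject_id = Path(matrix_source).stem
    return WeightedConnectome(tuple(labels), wdf.to_numpy(dtype=float), fa, subject_id)


def save_connectome(c: WeightedConnectome, matrix_path: str | Path,
                    fa_path: str | Path | None = None) -> None:
    """Write the labelled matrix (and FA) in the TSV format of
    :func:`load_connectome`."""
    w = c.weights
    if np.allclose(w, np.round(w)):
        w = w.astype(int)
    pd.DataFrame(w, index=c.node_labels, columns=c.node_labels).to_csv(
        matrix_path, sep="\t"
    )
    if fa_path is not None:
        if c.fa is None:
            raise ConnectomeError("connectome has no FA matrix to save")
        pd.DataFrame(c.fa, index=c.node_labels, columns=c.node_labels).to_csv(
            fa_path, sep="\t"
        )


def load_edge_list(
    edges_source: str | Path,
    labels: Sequence[str],
    subject_id: str = "",
) -> WeightedConnectome:
    """Build a connectome from a 3-column (label_i, label_j, weight)
    edge list plus an explicit label ordering."""
    df = pd.read_csv(edges_source, sep=None, engine="python", header=None,
                     names=["i", "j", "w"])
    labels = [str(x) for x in labels]
    idx = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    w = np.zeros((n, n))
    for _, row in df.iterrows():
        a, b = str(row["i"]), str(row["j"])
        if a not in idx or b not in idx:
            missing = a if a not in idx else b
            raise ConnectomeError(f"edge-list label {missing!r} not in label file")
        w[idx[a], idx[b]] = row["w"]
        w[idx[b], idx[a]] = row["w"]
    return WeightedConnectome(tuple(labels), w, None, subject_id)


# ---------------------------------------------------------------------------
# Thresholding, hubs, subnetworks
# ---------------------------------------------------------------------------

def threshold_edges(
    c: WeightedConnectome,
    min_streamlines: int = DEFAULT_STREAMLINE_THRESHOLD,
) -> WeightedConnectome:
    """Remove edges carried by fewer than ``min_streamlines`` streamlines.

    Surviving edges keep their weight; removed edges are zeroed in both
    the weight and FA matrices.  Idempotent.
    """
    if min_streamlines < 1:
        raise ValueError("min_streamlines must be >= 1")
    keep = c.weights >= min_streamlines
    w = np.where(keep, c.weights, 0.0)
    fa = np.where(keep, c.fa, 0.0) if c.fa is not None else None
    return WeightedConnectome(c.node_labels, w, fa, c.subject_id)


def identify_hubs(
    c: WeightedConnectome,
    degree_threshold: int = DEFAULT_HUB_DEGREE_THRESHOLD,
) -> frozenset[str]:
    """Nodes whose degree is STRICTLY greater than ``degree_threshold``."""
    deg = c.degree()
    return frozenset(
        lab for lab, k in zip(c.node_labels, deg) if k > degree_threshold
    )


def hub_attached_subnetwork(
    c: WeightedConnectome, nd: NetworkDefinition
) -> WeightedConnectome:
    """Induced subgraph over hubs ∪ reading-network nodes.

    Edge weights are copied from the parent matrix; no re-thresholding.
    """
    if nd.pivot_node not in c.node_labels:
        raise ConnectomeError(f"pivot node {nd.pivot_node!r} absent from connectome")
    missing = sorted(nd.subnetwork_nodes - set(c.node_labels))
    if missing:
        raise ConnectomeError(f"subnetwork nodes absent from connectome: {missing}")
    keep = [lab for lab in c.node_labels if lab in nd.subnetwork_nodes]
    ix = np.array([c.index_of(lab) for lab in keep])
    w = c.weights[np.ix_(ix, ix)]
    fa = c.fa[np.ix_(ix, ix)] if c.fa is not None else None
    return WeightedConnectome(tuple(keep), w, fa, c.subject_id)


def mean_edge_fa(
    c: WeightedConnectome,
    scope: str = "subnetwork",
    pivot: str = LEFT_THALAMUS,
) -> float:
    """Mean FA over existing edges, each undirected edge counted once.

    ``scope="subnetwork"`` averages over every edge of ``c`` (pass the
    hub-attached subnetwork to reproduce the covariate used in the
    correlation analyses); ``scope="pivot-incident"`` averages only over
    edges incident to the pivot node (the thalamocortical-connection
    covariate of the regression models).
    """
    if c.fa is None:
        raise ConnectomeError("connectome has no FA matrix")
    if scope == "subnetwork":
        mask = np.triu(c.weights, k=1) > 0
    elif scope == "pivot-incident":
        p = c.index_of(pivot)
        mask = np.zeros_like(c.weights, dtype=bool)
        mask[p, :] = c.weights[p, :] > 0
        mask = np.triu(mask | mask.T, k=1)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if not mask.any():
        raise ConnectomeError(f"no edges in scope {scope!r}")
    return float(c.fa[mask].mean())


# ---------------------------------------------------------------------------
# Probabilistic-index and tracking-success utilities
# ---------------------------------------------------------------------------

def normalized_connectivity_index(waytotal: int, v_seed: int) -> float:
    """``log(waytotal) / log(5000 * v_seed)`` — base independent.

    5000 probabilistic samples are generated per seed voxel, so the
    denominator is the (log of the) maximum attainable streamline count;
    waytotal = 1 maps to 0 and waytotal = 5000·v_seed maps to 1.
    """
    if v_seed < 1:
        raise ValueError("v_seed must be a positive voxel count")
    if waytotal < 1:
        raise ValueError(
            "waytotal must be >= 1 (0 means no connection; handle upstream)"
        )
    return float(np.log(waytotal) / np.log(5000.0 * v_seed))


def tracking_success_rate(
    connected: Iterable[bool],
    denominator: int | None = None,
) -> float:
    """Percentage of subjects with >= 1 surviving seed-to-target connection.

    ``connected`` holds per-subject indicators computed AFTER streamline
    thresholding.  ``denominator`` defaults to the number of indicators;
    an explicit value supports cohort-level denominators.
    """
    flags = [bool(x) for x in connected]
    if not flags:
        raise ValueError("need at least one subject")
    denom = len(flags) if denominator is None else denominator
    if denom < 1:
        raise ValueError("denominator must be positive")
    return 100.0 * sum(flags) / denom
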