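"""Degree/strength/weight-preserving random networks and cost
normalization.

The empirical communication costs are compared against randomized
counterparts that keep each node's degree, the global edge-weight
multiset, and (approximately) each node's strength.  Randomization is
two-stage: degree-preserving double-edge swaps rewire the topology, then
the original weight multiset is reassigned onto the new edges,
rank-matched to expected strengths and refined by local exchange passes
that shrink per-node strength error.

Normalized curves ‖C‖(λ) = C_emp(λ) / mean_ensemble C_rand(λ) define the
"efficient" λ window: grid points where the empirical network
communicates more cheaply than chance (‖C‖ < 1, strict).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netcore import WeightedConnectome
from .routing import CostSpectrum, LambdaGrid, ThalamicCost, cost_spectrum

logger = logging.getLogger(__name__)

DEFAULT_ENSEMBLE_SIZE = 500
DEFAULT_SWAPS_PER_EDGE = 10
_REFINE_PASSES = 20

#: Fixed cost-averaging windows on ln λ (closed intervals).
FIXED_WINDOW_TRANS = (-5.1, 0.15)
FIXED_WINDOW_INFO = (-0.14, 2.76)


@dataclass(frozen=True)
class NullEnsemble:
    parent_subject: str
    members: tuple[WeightedConnectome, ...]
    seed: int
    swap_count: int

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class NormalizedCostSpectrum:
    """Empirical/ensemble cost ratios per λ and the efficient windows."""

    grid: LambdaGrid
    ratio_trans: np.ndarray
    ratio_info: np.ndarray

    def efficient_window(self, kind: str) -> np.ndarray:
        """Boolean mask of grid points with ratio strictly below 1."""
        if kind == "trans":
            return np.isfinite(self.ratio_trans) & (self.ratio_trans < 1.0)
        if kind == "info":
            return np.isfinite(self.ratio_info) & (self.ratio_info < 1.0)
        raise ValueError(f"unknown cost kind {kind!r}")


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------

def randomize_network(
    c: WeightedConnectome,
    n_swap_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
) -> WeightedConnectome:
    """One randomized counterpart of ``c``.

    Preserves the degree sequence and the edge-weight multiset exactly;
    node strengths approximately (rank-matched weight assignment plus
    exchange refinement).
    """
    edges = c.edge_list()
    m = len(edges)
    if m < 2:
        warnings.warn("graph too small to swap; returning a copy")
        return WeightedConnectome(c.node_labels, c.weights.copy(), None,
                                  c.subject_id)
    rng = np.random.default_rng(seed)
    g = nx.Graph(edges)
    g.add_nodes_from(range(c.n_nodes))
    # small dense graphs may not admit the requested number of swaps;
    # back off rather than fail (the achieved swap count still randomizes)
    for nswap in (n_swap_per_edge * m, m, max(1, m // 4)):
        g_try = g.copy()
        try:
            nx.double_edge_swap(g_try, nswap=nswap, max_tries=200 * nswap,
                                seed=int(rng.integers(2**31 - 1)))
            g = g_try
            break
        except nx.NetworkXException:
            continue
    else:
        warnings.warn("edge swapping failed; returning a copy")
        return WeightedConnectome(c.node_labels, c.weights.copy(), None,
                                  c.subject_id)
    new_edges = np.array(sorted(tuple(sorted(e)) for e in g.edges()))
    weights_pool = np.sort(c.weights[tuple(np.array(edges).T)])[::-1]

    # rank-match: edges whose endpoints had high parent strength receive
    # the large weights
    parent_strength = c.strength()
    score = (parent_strength[new_edges[:, 0]]
             + parent_strength[new_edges[:, 1]])
    order = np.argsort(-score, kind="stable")
    assigned = np.empty(m)
    assigned[order] = weights_pool

    # local exchange passes: swap weight pairs when that reduces the
    # summed absolute strength error
    s_target = parent_strength
    inc = np.zeros((c.n_nodes, m))
    inc[new_edges[:, 0], np.arange(m)] = 1
    inc[new_edges[:, 1], np.arange(m)] = 1
    s_cur = inc @ assigned
    for _ in range(_REFINE_PASSES):
        a = rng.integers(0, m, size=m)
        b = rng.integers(0, m, size=m)
        improved = False
        for e1, e2 in zip(a, b):
            if e1 == e2 or assigned[e1] == assigned[e2]:
                continue
            delta_w = assigned[e2] - assigned[e1]
            nodes = {int(new_edges[e1, 0]), int(new_edges[e1, 1]),
                     int(new_edges[e2, 0]), int(new_edges[e2, 1])}
            old = sum(abs(s_cur[v] - s_target[v]) for v in nodes)
            s_new = {}
            for v in nodes:
                dv = 0.0
                if v in (new_edges[e1, 0], new_edges[e1, 1]):
                    dv += delta_w
                if v in (new_edges[e2, 0], new_edges[e2, 1]):
                    dv -= delta_w
                s_new[v] = s_cur[v] + dv
            new = sum(abs(s_new[v] - s_target[v]) for v in nodes)
            if new < old:
                assigned[e1], assigned[e2] = assigned[e2], assigned[e1]
                for v, sv in s_new.items():
                    s_cur[v] = sv
                improved = True
        if not improved:
            break

    w = np.zeros_like(c.weights)
    w[new_edges[:, 0], new_edges[:, 1]] = assigned
    w[new_edges[:, 1], new_edges[:, 0]] = assigned
    return WeightedConnectome(c.node_labels, w, None, c.subject_id)


def null_ensemble(
    c: WeightedConnectome,
    n_members: int = DEFAULT_ENSEMBLE_SIZE,
    n_swap_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
) -> NullEnsemble:
    """Seeded ensemble of randomized counterparts of one subject."""
    ss = np.random.SeedSequence(seed)
    members = tuple(
        randomize_network(c, n_swap_per_edge, int(child.generate_state(1)[0] % (2**31)))
        for child in ss.spawn(n_members)
    )
    return NullEnsemble(c.subject_id, members, seed,
                        n_swap_per_edge * len(c.edge_list()))


# ---------------------------------------------------------------------------
# Normalization and windows
# ---------------------------------------------------------------------------

def normalized_cost_curves(
    emp: CostSpectrum,
    ensemble: NullEnsemble,
    pairs: list[tuple[str, str]],
    grid: LambdaGrid | None = None,
    length_transform: str = "reciprocal",
    aggregate: str = "mean",
) -> NormalizedCostSpectrum:
    """‖C‖(λ) = empirical pair-averaged cost / ensemble aggregate of the
    pair-averaged cost, per λ and cost kind."""
    if grid is None:
        grid = emp.grid
    emp_t, emp_i = emp.mean_curves()
    curves_t, curves_i = [], []
    for member in ensemble.members:
        spec = cost_spectrum(member, pairs, grid, length_transform)
        mt, mi = spec.mean_curves()
        curves_t.append(mt)
        curves_i.append(mi)
    agg = np.mean if aggregate == "mean" else np.median
    rand_t = agg(np.asarray(curves_t), axis=0)
    rand_i = agg(np.asarray(curves_i), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rt = emp_t / rand_t
        ri = emp_i / rand_i
    bad = ~np.isfinite(rt) | ~np.isfinite(ri)
    if bad.any():
        logger.warning("%d grid point(s) excluded (nonfinite ensemble cost)",
                       int(bad.sum()))
        rt = np.where(np.isfinite(rt), rt, np.nan)
        ri = np.where(np.isfinite(ri), ri, np.nan)
    return NormalizedCostSpectrum(grid, rt, ri)


def efficient_lambda_window(
    ncs: NormalizedCostSpectrum, kind: str
) -> np.ndarray:
    """Grid mask where the empirical network beats its nulls (ratio < 1)."""
    mask = ncs.efficient_window(kind)
    if not mask.any():
        warnings.warn(f"no grid point with ‖C^{kind}‖ < 1; empty window")
    return mask


def window_average_cost(
    values: np.ndarray,
    grid: LambdaGrid,
    window: np.ndarray | tuple[float, float],
) -> float:
    """Arithmetic mean of a per-λ curve over a window.

    ``window`` is either a boolean grid mask (data-driven) or a closed
    ``(lo, hi)`` interval on ln λ (the fixed published windows).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_steps,):
        raise ValueError("curve length does not match grid")
    if isinstance(window, tuple):
        mask = grid.window_mask(*window)
    else:
        mask = np.asarray(window, dtype=bool)
        if mask.shape != (grid.n_steps,):
            raise ValueError("window mask length does not match grid")
    if not mask.any():
        raise ValueError("empty λ window; supply a data-driven or fixed window")
    return float(values[mask].mean())


def thalamic_window_average(
    tc: ThalamicCost,
    kind: str,
    window: np.ndarray | tuple[float, float] | None = None,
) -> float:
    """Window-averaged pivot cost scalar (the per-subject statistic
    correlated with reading scores)."""
    if window is None:
        window = FIXED_WINDOW_TRANS if kind == "trans" else FIXED_WINDOW_INFO
    return window_average_cost(tc.total(kind), tc.grid, window)
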