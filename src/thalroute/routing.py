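"""λ-tuned stochastic routing: transition models, communication costs.

A signal travelling from source X to target T performs a biased random
walk whose transition probabilities blend local edge lengths d_ij with
global shortest-path-to-target distances g_jt:

    P_λ(Y=j | X=i, T=t)  ∝  exp(−(λ (d_ij + g_jt) + d_ij))

normalized over the neighbours j of i.  λ = 0 is an unbiased,
locally-weighted walk; λ → ∞ concentrates on the shortest-path
successor.  Two costs characterise each strategy:

* transmission cost C^trans — the expected walked distance from source
  to target (absorbing-Markov-chain expectation), and
* informational cost C^info — the expected number of bits (KL divergence
  from the λ = 0 null walk, accumulated over expected node visits)
  needed to execute the biased strategy.

Costs are directional: cost(s→t) uses the t-specific transition model
and generally differs from cost(t→s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .netcore import NetworkDefinition, WeightedConnectome
from .nodal_metrics import (
    GeodesicMatrix,
    LengthMatrix,
    geodesic_matrix,
    weight_to_length,
)

logger = logging.getLogger(__name__)

#: Default ln λ grid: spans both cost-averaging windows.
DEFAULT_GRID_BOUNDS = (-5.1, 2.76)
#: Alternative published-convention grid preset.
PUBLISHED_GRID_BOUNDS = (-2.2, 1.45)
DEFAULT_GRID_STEPS = 30

_SOLVE_TOL = 1e-10


@dataclass(frozen=True)
class LambdaGrid:
    """Equally spaced grid on ln λ."""

    ln_lambda_values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.ln_lambda_values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("grid must be a 1-d array of ln lambda values")
        if v.size > 1:
            steps = np.diff(v)
            if np.any(steps <= 0):
                raise ValueError("ln lambda grid must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-8):
                raise ValueError("ln lambda grid must be equally spaced")
        object.__setattr__(self, "ln_lambda_values", v)

    @property
    def n_steps(self) -> int:
        return self.ln_lambda_values.size

    @classmethod
    def default(cls, n_steps: int = DEFAULT_GRID_STEPS) -> "LambdaGrid":
        lo, hi = DEFAULT_GRID_BOUNDS
        return cls(np.linspace(lo, hi, n_steps))

    @classmethod
    def published_preset(cls, n_steps: int = DEFAULT_GRID_STEPS) -> "LambdaGrid":
        lo, hi = PUBLISHED_GRID_BOUNDS
        return cls(np.linspace(lo, hi, n_steps))

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points with lo <= ln λ <= hi (inclusive)."""
        v = self.ln_lambda_values
        return (v >= lo - 1e-12) & (v <= hi + 1e-12)


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic transitions toward one target at one λ.

    ``probabilities[i, j]`` is P(next = j | at i) for transient i; the
    target row is absorbing.  Nodes without a finite-geodesic route to
    the target are excluded from the transient set (``excluded``).
    """

    target: int
    ln_lambda: float
    probabilities: np.ndarray
    normalizers: np.ndarray
    transient: np.ndarray          # sorted transient node indices
    excluded: tuple[int, ...]      # nodes with no route to target
    node_labels: tuple[str, ...]


def transition_model(
    d: LengthMatrix,
    g: GeodesicMatrix,
    ln_lambda: float,
    target: int | str,
    null: bool = False,
    uniform_null: bool = False,
) -> TransitionModel:
    """Build the λ-tuned (or null) transition model toward ``target``.

    ``null=True`` gives the λ = 0 strategy P ∝ exp(−d_ij) (the unbiased
    end of the spectrum); ``uniform_null=True`` a uniform choice over
    neighbours.  Exponent rows are shifted by their maximum before
    exponentiation so large λ cannot underflow to an all-zero row.
    """
    labels = d.node_labels
    t = labels.index(target) if isinstance(target, str) else int(target)
    n = d.n_nodes
    lengths = d.lengths
    adj = d.adjacency()
    gt = g.g[:, t]

    lam = 0.0 if null or uniform_null else float(np.exp(ln_lambda))
    # mass only on neighbours that can still reach the target
    valid = adj & np.isfinite(gt)[None, :]
    D = np.where(valid, lengths, 0.0)
    G = np.where(valid, gt[None, :], 0.0)
    if uniform_null:
        expo = np.where(valid, 0.0, -np.inf)
    else:
        expo = np.where(valid, -(lam * (D + G) + D), -np.inf)
    has_route = valid.any(axis=1)
    # log-sum-exp shift per row so large λ cannot underflow every entry
    shift = np.where(has_route, expo.max(axis=1, initial=-np.inf), 0.0)
    with np.errstate(invalid="ignore"):
        raw = np.exp(expo - shift[:, None])
    raw[~valid] = 0.0
    rowsum = raw.sum(axis=1)
    P = np.zeros((n, n))
    ok = rowsum > 0
    P[ok] = raw[ok] / rowsum[ok, None]
    Z = np.where(ok, rowsum * np.exp(shift), 0.0)
    P[t, :] = 0.0
    P[t, t] = 1.0
    excluded = [int(i) for i in np.flatnonzero(~has_route) if i != t]
    transient = np.array([i for i in range(n) if i != t and i not in excluded],
                         dtype=int)
    if excluded:
        logger.debug("target %s: %d nodes excluded (no route)", labels[t],
                     len(excluded))
    return TransitionModel(t, float(ln_lambda), P, Z, transient,
                           tuple(excluded), labels)


# ---------------------------------------------------------------------------
# Absorbing-chain expectations
# ---------------------------------------------------------------------------

def _transient_system(tm: TransitionModel) -> tuple[np.ndarray, np.ndarray]:
    """(I − Q) over the transient set, plus the transient index array."""
    tr = tm.transient
    Q = tm.probabilities[np.ix_(tr, tr)]
    A = np.eye(tr.size) - Q
    return A, tr


def _solve_costs(tm: TransitionModel, per_visit: np.ndarray) -> np.ndarray:
    """Solve x = per_visit + Q x; returns x indexed over ALL nodes
    (inf for excluded, 0 at the target)."""
    A, tr = _transient_system(tm)
    n = len(tm.node_labels)
    out = np.full(n, np.inf)
    out[tm.target] = 0.0
    if tr.size:
        try:
            lu = lu_factor(A)
        except Exception as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(
                f"singular transient system for target "
                f"{tm.node_labels[tm.target]}: {exc}"
            ) from exc
        x = lu_solve(lu, per_visit[tr])
        resid = np.abs(A @ x - per_visit[tr]).max() if tr.size else 0.0
        if not np.isfinite(x).all() or resid > _SOLVE_TOL * max(1.0, np.abs(x).max()):
            raise np.linalg.LinAlgError(
                f"non-absorbing transient system for target "
                f"{tm.node_labels[tm.target]} (residual {resid:.3g})"
            )
        out[tr] = x
    return out


def _expected_step_lengths(tm: TransitionModel, d: LengthMatrix) -> np.ndarray:
    """b_i = Σ_j P_ij d_ij, the expected length of one step from i
    (includes the absorbing step into the target)."""
    P = tm.probabilities
    lengths = np.where(np.isfinite(d.lengths), d.lengths, 0.0)
    return np.einsum("ij,ij->i", P, lengths)


def transmission_cost(
    tm: TransitionModel, d: LengthMatrix, source: int | str
) -> float:
    """Expected walked distance from ``source`` to the target."""
    s = (tm.node_labels.index(source) if isinstance(source, str) else int(source))
    if s == tm.target:
        return 0.0
    if s in tm.excluded:
        raise ValueError(f"source {tm.node_labels[s]!r} cannot reach the target")
    return float(_solve_costs(tm, _expected_step_lengths(tm, d))[s])


def _row_kl_bits(tm: TransitionModel, null_tm: TransitionModel) -> np.ndarray:
    """Per-node KL(tm row ‖ null row) in bits."""
    P, P0 = tm.probabilities, null_tm.probabilities
    support = P > 0
    viol = support & (P0 <= 0)
    viol[tm.target, :] = False
    if np.any(viol):
        i, j = np.argwhere(viol)[0]
        raise ValueError(
            f"null model lacks support at edge "
            f"({tm.node_labels[i]}, {tm.node_labels[j]})"
        )
    kl = np.zeros(P.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(support, P / np.where(P0 > 0, P0, 1.0), 1.0)
        kl_terms = np.where(support, P * np.log2(ratio), 0.0)
    kl[:] = kl_terms.sum(axis=1)
    kl[tm.target] = 0.0
    return kl


def informational_cost(
    tm: TransitionModel, null_tm: TransitionModel, source: int | str
) -> float:
    """Expected bits of divergence from the null walk, source → target.

    Σ over transient nodes of (expected visits under ``tm`` starting at
    ``source``) × KL(tm row ‖ null row), in bits.
    """
    if null_tm.target != tm.target:
        raise ValueError("null model must share the target")
    s = (tm.node_labels.index(source) if isinstance(source, str) else int(source))
    if s == tm.target:
        return 0.0
    if s in tm.excluded:
        raise ValueError(f"source {tm.node_labels[s]!r} cannot reach the target")
    return float(_solve_costs(tm, _row_kl_bits(tm, null_tm))[s])


def expected_visits(tm: TransitionModel, source: int | str) -> np.ndarray:
    """Fundamental-matrix row: expected visits to each node of a walk
    from ``source`` before absorption (source counts its initial visit)."""
    s = (tm.node_labels.index(source) if isinstance(source, str) else int(source))
    A, tr = _transient_system(tm)
    pos = {int(i): k for k, i in enumerate(tr)}
    if s not in pos:
        raise ValueError("source not in transient set")
    e = np.zeros(tr.size)
    e[pos[s]] = 1.0
    nu = np.linalg.solve(A.T, e)
    out = np.zeros(len(tm.node_labels))
    out[tr] = nu
    return out


# ---------------------------------------------------------------------------
# Spectra over the λ grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostSpectrum:
    """Per-pair, per-λ transmission and informational costs."""

    pairs: tuple[tuple[str, str], ...]
    grid: LambdaGrid
    c_trans: np.ndarray  # (n_pairs, n_lambda)
    c_info: np.ndarray   # (n_pairs, n_lambda)
    node_labels: tuple[str, ...]
    n_unreachable: int = 0

    def mean_curves(self) -> tuple[np.ndarray, np.ndarray]:
        """Pair-averaged cost curves, skipping unreachable (inf) pairs."""
        with np.errstate(invalid="ignore"):
            mt = np.nanmean(np.where(np.isfinite(self.c_trans), self.c_trans,
                                     np.nan), axis=0)
            mi = np.nanmean(np.where(np.isfinite(self.c_info), self.c_info,
                                     np.nan), axis=0)
        return mt, mi

    def pair_index(self, source: str, target: str) -> int:
        try:
            return self.pairs.index((source, target))
        except ValueError:
            raise KeyError(f"pair ({source!r}, {target!r}) not in spectrum") from None


def all_pairs(labels: tuple[str, ...] | list[str]) -> list[tuple[str, str]]:
    """All ordered pairs of distinct labels."""
    return [(s, t) for t in labels for s in labels if s != t]


def reading_pivot_pairs(nd: NetworkDefinition) -> list[tuple[str, str]]:
    """The region↔pivot pair list needed by :func:`thalamic_cost`."""
    regions = sorted(nd.reading_nodes - {nd.pivot_node})
    return ([(r, nd.pivot_node) for r in regions]
            + [(nd.pivot_node, r) for r in regions])


def cost_spectrum(
    c: WeightedConnectome,
    pairs: list[tuple[str, str]],
    grid: LambdaGrid | None = None,
    length_transform: str = "reciprocal",
    uniform_null: bool = False,
) -> CostSpectrum:
    """Both communication costs for every requested (source, target)
    pair at every grid point.

    One linear solve per (target, λ) yields the costs from all sources
    simultaneously.  Unreachable pairs are recorded as inf and skipped
    by the averaged curves.
    """
    if grid is None:
        grid = LambdaGrid.default()
    d = weight_to_length(c, length_transform)
    g = geodesic_matrix(d)
    labels = c.node_labels
    by_target: dict[str, list[int]] = {}
    for k, (_, t) in enumerate(pairs):
        by_target.setdefault(t, []).append(k)

    npairs, nl = len(pairs), grid.n_steps
    ct = np.full((npairs, nl), np.inf)
    ci = np.full((npairs, nl), np.inf)
    n_unreach = 0
    for tgt, pair_idx in by_target.items():
        null_tm = transition_model(d, g, 0.0, tgt, null=True,
                                   uniform_null=uniform_null)
        for li, ln_lam in enumerate(grid.ln_lambda_values):
            tm = transition_model(d, g, ln_lam, tgt)
            xt = _solve_costs(tm, _expected_step_lengths(tm, d))
            xi = _solve_costs(tm, _row_kl_bits(tm, null_tm))
            for k in pair_idx:
                s = labels.index(pairs[k][0])
                ct[k, li] = xt[s]
                ci[k, li] = xi[s]
        unreachable = [k for k in pair_idx
                       if not np.isfinite(ct[k]).all()]
        n_unreach += len(unreachable)
    if n_unreach:
        logger.warning("%d pair(s) unreachable; excluded from averages",
                       n_unreach)
    return CostSpectrum(tuple((s, t) for s, t in pairs), grid, ct, ci,
                        labels, n_unreach)


# ---------------------------------------------------------------------------
# Thalamus-pivot aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThalamicCost:
    """Per-λ cost of reading-network communication routed via the pivot:
    total = Σ_regions cost(region→pivot) + Σ_regions cost(pivot→region)."""

    pivot: str
    regions: tuple[str, ...]
    grid: LambdaGrid
    c_to_pivot_trans: np.ndarray
    c_from_pivot_trans: np.ndarray
    c_to_pivot_info: np.ndarray
    c_from_pivot_info: np.ndarray

    def total(self, kind: str, aggregate: str = "sum") -> np.ndarray:
        if kind == "trans":
            tot = self.c_to_pivot_trans + self.c_from_pivot_trans
        elif kind == "info":
            tot = self.c_to_pivot_info + self.c_from_pivot_info
        else:
            raise ValueError(f"unknown cost kind {kind!r}")
        if aggregate == "sum":
            return tot
        if aggregate == "mean":
            return tot / (2 * len(self.regions))
        raise ValueError(f"unknown aggregate {aggregate!r}")


def thalamic_cost(spec: CostSpectrum, nd: NetworkDefinition) -> ThalamicCost:
    """Aggregate a spectrum through the pivot (left thalamus)."""
    regions = tuple(sorted(nd.reading_nodes - {nd.pivot_node}))
    missing = [
        p for r in regions
        for p in ((r, nd.pivot_node), (nd.pivot_node, r))
        if p not in spec.pairs
    ]
    if missing:
        raise ValueError(f"spectrum missing pivot pairs: {missing}")
    to_t = np.zeros(spec.grid.n_steps)
    from_t = np.zeros(spec.grid.n_steps)
    to_i = np.zeros(spec.grid.n_steps)
    from_i = np.zeros(spec.grid.n_steps)
    for r in regions:
        k_in = spec.pair_index(r, nd.pivot_node)
        k_out = spec.pair_index(nd.pivot_node, r)
        to_t += spec.c_trans[k_in]
        from_t += spec.c_trans[k_out]
        to_i += spec.c_info[k_in]
        from_i += spec.c_info[k_out]
    return ThalamicCost(nd.pivot_node, regions, spec.grid,
                        to_t, from_t, to_i, from_i)


# ---------------------------------------------------------------------------
# Monte-Carlo walk oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WalkEstimate:
    """Empirical walk statistics.

    ``mean_log2_ratio`` accumulates the sampled log₂ probability ratio of
    each transition (high variance); ``mean_visit_kl`` accumulates the
    per-visit expected KL of the occupied row (same expectation, visits
    estimated by simulation, far lower variance).
    """

    mean_distance: float
    mean_log2_ratio: float
    mean_visit_kl: float
    n_walks: int
    n_truncated: int


def simulate_walks(
    tm: TransitionModel,
    d: LengthMatrix,
    source: int | str,
    n_walks: int,
    seed: int,
    max_steps: int = 10_000,
    null_tm: TransitionModel | None = None,
) -> WalkEstimate:
    """Empirical transmission / informational cost by simulating
    absorbing walks (vectorised across walks).

    Returns the mean walked distance and, if ``null_tm`` is given, the
    mean accumulated log₂ probability ratio versus the null strategy.
    Walks still unabsorbed after ``max_steps`` are counted separately.
    """
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    s = (tm.node_labels.index(source) if isinstance(source, str) else int(source))
    rng = np.random.default_rng(seed)
    n = len(tm.node_labels)
    P = tm.probabilities
    cumP = np.cumsum(P, axis=1)
    lengths = np.where(np.isfinite(d.lengths), d.lengths, 0.0)
    logratio = np.zeros_like(P)
    if null_tm is not None:
        mask = P > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = np.log2(np.where(mask, P, 1.0)
                         / np.where(mask & (null_tm.probabilities > 0),
                                    null_tm.probabilities, 1.0))
        logratio = np.where(mask, lr, 0.0)
        logratio[tm.target, :] = 0.0
        kl_row = _row_kl_bits(tm, null_tm)
    else:
        kl_row = np.zeros(n)

    cur = np.full(n_walks, s, dtype=np.int64)
    dist = np.zeros(n_walks)
    bits = np.zeros(n_walks)
    visit_kl = np.zeros(n_walks)
    active = cur != tm.target
    steps = 0
    while active.any() and steps < max_steps:
        idx = np.flatnonzero(active)
        if null_tm is not None:
            visit_kl[idx] += kl_row[cur[idx]]
        u = rng.random(idx.size)
        nxt = np.empty(idx.size, dtype=np.int64)
        for node in np.unique(cur[idx]):
            m = cur[idx] == node
            nxt[m] = np.searchsorted(cumP[node], u[m], side="right")
        nxt = np.minimum(nxt, n - 1)
        dist[idx] += lengths[cur[idx], nxt]
        if null_tm is not None:
            bits[idx] += logratio[cur[idx], nxt]
        cur[idx] = nxt
        active[idx] = nxt != tm.target
        steps += 1
    n_trunc = int(active.sum())
    done = ~active
    if not done.any():
        raise RuntimeError("no walk reached the target within max_steps")
    if n_trunc:
        logger.warning("%d/%d walks truncated at %d steps", n_trunc,
                       n_walks, max_steps)
    return WalkEstimate(float(dist[done].mean()), float(bits[done].mean()),
                        float(visit_kl[done].mean()), n_walks, n_trunc)
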