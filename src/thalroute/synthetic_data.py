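"""Synthetic connectome cohorts and closed-form toy graphs.

The generator emulates the statistical structure the analysis needs —
90-node AAL-labelled symmetric integer-weight connectomes with a dense
hub core and peripheral modules, per-subject multiplicative weight
jitter, per-edge FA, demographic covariates, and reading scores with a
planted linear association to a pipeline-computed network metric.  It
makes no attempt at geometric or diffusion-signal realism.

Scores are drawn as  score = mean + sd · (ρ·z_metric + √(1−ρ²)·ε)  with
z_metric the across-subject standardization of the target metric, so the
planted population correlation between metric and score is exactly ρ and
recovery tests exercise the same estimator used on real cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import netcore
from .netcore import (
    NetworkDefinition,
    WeightedConnectome,
    hub_attached_subnetwork,
    identify_hubs,
    mean_edge_fa,
    reading_network_labels,
    threshold_edges,
)
from .nodal_metrics import clustering_coefficient, local_efficiency
from .nullmodels import (
    FIXED_WINDOW_INFO,
    FIXED_WINDOW_TRANS,
    thalamic_window_average,
)
from .routing import LambdaGrid, cost_spectrum, reading_pivot_pairs, thalamic_cost

#: Cohort-level score distributions emulated for the non-target scores
#: (standard-score mean/SD as observed in school-age reading cohorts).
SCORE_DISTRIBUTIONS = {
    "swe_std": (93.0, 21.3),
    "pde_std": (92.7, 19.8),
    "pc_std": (90.0, 13.3),
    "ran_items_per_sec": (1.87, 0.48),
}

_HUB_TARGET_DEGREE = 26
_PERIPHERY_DEGREE_CAP = 18


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_subjects: int = 64
    n_nodes: int = 90
    planted_rho: float = 0.4
    target_metric: str = "c_thal_trans"
    score_name: str = "pde_std"
    score_mean: float = 100.0
    score_sd: float = 15.0
    covariate_effects: dict = field(default_factory=dict)
    network: str = "hub-attached"
    density: float = 0.10
    n_hubs: int = 6
    weight_jitter_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.planted_rho < 1.0:
            raise ValueError("|planted_rho| must be < 1")
        if self.n_subjects < 8:
            raise ValueError("n_subjects must exceed covariate count + 3")
        if self.score_name not in SCORE_DISTRIBUTIONS:
            raise ValueError(f"unknown score {self.score_name!r}")


@dataclass(frozen=True)
class ToyFixture:
    name: str
    node_labels: tuple[str, ...]
    weights: np.ndarray
    expected: dict

    def connectome(self) -> WeightedConnectome:
        return WeightedConnectome(self.node_labels, self.weights,
                                  subject_id=f"toy_{self.name}")


# ---------------------------------------------------------------------------
# Single-connectome generator
# ---------------------------------------------------------------------------

def generate_connectome(
    n_nodes: int = 90,
    density: float = 0.10,
    n_hubs: int = 6,
    weight_range: tuple[int, int] = (3, 60),
    seed: int = 0,
    labels: tuple[str, ...] | None = None,
    attach_labels: tuple[str, ...] = (),
) -> WeightedConnectome:
    """Seed-deterministic hub-core + peripheral-module connectome.

    Planted hubs end with degree > 20 and every other node stays at or
    below {cap}; the graph is connected after thresholding at 3 because
    every planted edge carries at least 3 streamlines and a ring spans
    all nodes.  Sub-threshold "false-positive" edges (weight 1–2) are
    sprinkled on non-edges and vanish at thresholding.
    """.format(cap=_PERIPHERY_DEGREE_CAP)
    if density <= 0:
        raise ValueError("density must be positive")
    if n_hubs >= n_nodes:
        raise ValueError("n_hubs must be < n_nodes")
    if n_hubs > 0 and n_nodes < _HUB_TARGET_DEGREE + 2:
        raise ValueError(
            f"cannot plant degree-{_HUB_TARGET_DEGREE} hubs in a "
            f"{n_nodes}-node graph"
        )
    lo, hi = weight_range
    if lo < netcore.DEFAULT_STREAMLINE_THRESHOLD:
        raise ValueError("weight_range minimum must be >= 3 (the edge threshold)")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = (tuple(netcore.aal90_labels()) if n_nodes == 90
                  else tuple(f"R{i:03d}" for i in range(n_nodes)))
    if len(labels) != n_nodes:
        raise ValueError("label count must equal n_nodes")

    order = rng.permutation(n_nodes)
    hubs = set(order[:n_hubs].tolist())
    periphery = [int(v) for v in order[n_hubs:]]

    adj = np.zeros((n_nodes, n_nodes), dtype=bool)

    def add(i: int, j: int) -> None:
        if i != j:
            adj[i, j] = adj[j, i] = True

    def deg(i: int) -> int:
        return int(adj[i].sum())

    # spanning ring guarantees connectivity
    ring = order.tolist()
    for a, b in zip(ring, ring[1:] + ring[:1]):
        add(int(a), int(b))

    # dense hub core
    hl = sorted(hubs)
    for ii, a in enumerate(hl):
        for b in hl[ii + 1:]:
            add(a, b)

    # attach periphery to hubs until each hub clears the degree bar
    for h in hl:
        candidates = [v for v in periphery
                      if not adj[h, v] and deg(v) < _PERIPHERY_DEGREE_CAP]
        rng.shuffle(candidates)
        for v in candidates:
            if deg(h) >= _HUB_TARGET_DEGREE:
                break
            add(h, v)
        if deg(h) <= netcore.DEFAULT_HUB_DEGREE_THRESHOLD:
            raise ValueError(
                "infeasible parameters: not enough periphery capacity to "
                "plant hubs (raise n_nodes or lower n_hubs)"
            )

    # guarantee named regions (e.g. the reading network) hang off the hub
    # core so hub-attached subnetworks stay connected
    if n_hubs > 0:
        for lab in attach_labels:
            v = labels.index(lab)
            if v in hubs:
                continue
            free = [h for h in hl if not adj[v, h]]
            rng.shuffle(free)
            for h in free[:2]:
                add(v, h)

    # peripheral modules with mostly-internal extra edges up to density
    n_modules = max(2, len(periphery) // 20)
    modules = [periphery[k::n_modules] for k in range(n_modules)]
    target_edges = int(density * n_nodes * (n_nodes - 1) / 2)
    tries = 0
    while adj.sum() // 2 < target_edges and tries < 50 * target_edges:
        tries += 1
        if rng.random() < 0.9:
            mod = modules[int(rng.integers(n_modules))]
            if len(mod) < 2:
                continue
            a, b = rng.choice(mod, size=2, replace=False)
        else:
            a, b = rng.choice(periphery, size=2, replace=False)
        a, b = int(a), int(b)
        if adj[a, b] or a == b:
            continue
        if deg(a) >= _PERIPHERY_DEGREE_CAP or deg(b) >= _PERIPHERY_DEGREE_CAP:
            continue
        add(a, b)

    w = np.zeros((n_nodes, n_nodes))
    iu, ju = np.nonzero(np.triu(adj, k=1))
    vals = rng.integers(lo, hi + 1, size=iu.size)
    w[iu, ju] = vals
    w[ju, iu] = vals

    # sub-threshold spurious edges
    n_noise = max(1, iu.size // 10)
    free_i, free_j = np.nonzero(np.triu(~adj, k=1))
    pick = rng.choice(free_i.size, size=min(n_noise, free_i.size), replace=False)
    nv = rng.integers(1, netcore.DEFAULT_STREAMLINE_THRESHOLD, size=pick.size)
    w[free_i[pick], free_j[pick]] = nv
    w[free_j[pick], free_i[pick]] = nv

    return WeightedConnectome(labels, w, None, subject_id=f"sim{seed:04d}")


def jitter_connectome(
    template: WeightedConnectome,
    sd: float,
    rng: np.random.Generator,
    subject_id: str,
    fa_mu: float | None = None,
) -> WeightedConnectome:
    """Integer-preserving multiplicative weight jitter of a template.

    Supra-threshold edges stay supra-threshold (topology is shared across
    subjects; weights vary log-normally).  If ``fa_mu`` is given, a
    per-edge FA matrix is drawn around it, truncated to [0.3, 0.6].
    """
    w = template.weights
    on = np.triu(w, k=1) > 0
    iu, ju = np.nonzero(on)
    vals = w[iu, ju]
    noise = np.exp(rng.normal(0.0, sd, size=vals.size))
    new = np.round(vals * noise)
    supra = vals >= netcore.DEFAULT_STREAMLINE_THRESHOLD
    # jitter never moves an edge across the streamline threshold, so the
    # thresholded topology is shared by every subject of a cohort
    new[supra] = np.maximum(new[supra], netcore.DEFAULT_STREAMLINE_THRESHOLD)
    new[~supra] = np.clip(new[~supra], 1,
                          netcore.DEFAULT_STREAMLINE_THRESHOLD - 1)
    out = np.zeros_like(w)
    out[iu, ju] = new
    out[ju, iu] = new
    fa = None
    if fa_mu is not None:
        f = np.clip(rng.normal(fa_mu, 0.03, size=vals.size), 0.3, 0.6)
        fa = np.zeros_like(w)
        fa[iu, ju] = f
        fa[ju, iu] = f
    return WeightedConnectome(template.node_labels, out, fa, subject_id)


# ---------------------------------------------------------------------------
# Metric plumbing used while planting associations
# ---------------------------------------------------------------------------

def reading_set_for(c: WeightedConnectome, pivot: str) -> tuple[str, ...]:
    """Ordered reading-region list for a connectome: the packaged AAL
    list when the labelling matches, otherwise the pivot's neighbourhood
    (small or generically-labelled test graphs).  The pivot comes last."""
    if pivot == netcore.LEFT_THALAMUS and (
            set(reading_network_labels("left")) <= set(c.node_labels)):
        regions = reading_network_labels("left")
    elif pivot == "Thalamus_R" and (
            set(reading_network_labels("right")) <= set(c.node_labels)):
        regions = reading_network_labels("right")
    else:
        ct = threshold_edges(c)
        p = ct.index_of(pivot)
        regions = [ct.node_labels[j]
                   for j in np.flatnonzero(ct.weights[p] > 0)[:12]]
        regions.append(pivot)
    return tuple([r for r in regions if r != pivot] + [pivot])


def compute_target_metric(
    c: WeightedConnectome,
    metric: str,
    network: str = "hub-attached",
    pivot: str = netcore.LEFT_THALAMUS,
    grid: LambdaGrid | None = None,
    mode: str = "weighted",
    reading_nodes: tuple[str, ...] | None = None,
) -> float:
    """Compute one analysis metric for one (already loaded) subject via
    the real pipeline: threshold → (optional) hub-attached subnetwork →
    metric."""
    ct = threshold_edges(c)
    if reading_nodes is None:
        reading_nodes = reading_set_for(c, pivot)
    nd = NetworkDefinition(
        hub_nodes=identify_hubs(ct),
        reading_nodes=frozenset(reading_nodes),
        pivot_node=pivot,
    )
    net = hub_attached_subnetwork(ct, nd) if network == "hub-attached" else ct
    if metric == "cc":
        return clustering_coefficient(net, pivot, mode)
    if metric == "le":
        return local_efficiency(net, pivot, mode)
    if metric in ("c_thal_trans", "c_thal_info"):
        if grid is None:
            grid = LambdaGrid.default()
        pairs = reading_pivot_pairs(nd)
        spec = cost_spectrum(net, pairs, grid)
        tc = thalamic_cost(spec, nd)
        kind = "trans" if metric.endswith("trans") else "info"
        window = FIXED_WINDOW_TRANS if kind == "trans" else FIXED_WINDOW_INFO
        return thalamic_window_average(tc, kind, window)
    raise ValueError(f"unknown target metric {metric!r}")


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[WeightedConnectome], pd.DataFrame]:
    """Generate connectomes plus a phenotype table with a planted
    metric–score correlation of ``spec.planted_rho``."""
    rng = np.random.default_rng(spec.seed)
    attach = (tuple(reading_network_labels("left")) if spec.n_nodes == 90
              else ())
    template = generate_connectome(
        n_nodes=spec.n_nodes,
        density=spec.density,
        n_hubs=spec.n_hubs,
        seed=int(rng.integers(2**31 - 1)),
        attach_labels=attach,
    )
    pivot = (netcore.LEFT_THALAMUS if spec.n_nodes == 90
             else template.node_labels[0])
    subjects = []
    fa_means = []
    for k in range(spec.n_subjects):
        mu = float(np.clip(rng.normal(0.45, 0.05), 0.3, 0.6))
        fa_means.append(mu)
        subjects.append(
            jitter_connectome(template, spec.weight_jitter_sd, rng,
                              subject_id=f"sub-{k + 1:03d}", fa_mu=mu)
        )

    reading = reading_set_for(template, pivot)
    metric = np.array([
        compute_target_metric(c, spec.target_metric, spec.network, pivot,
                              reading_nodes=reading)
        for c in subjects
    ])
    if metric.std() == 0:
        raise ValueError(
            "degenerate metric variance across subjects; increase weight_jitter_sd"
        )
    z = (metric - metric.mean()) / metric.std()

    n = spec.n_subjects
    age = rng.uniform(9.0, 14.0, size=n)
    sex = rng.integers(0, 2, size=n)
    handedness = (rng.random(size=n) < 0.95).astype(int)  # 1 = right

    rho = spec.planted_rho
    eps = rng.standard_normal(n)
    target_score = spec.score_mean + spec.score_sd * (
        rho * z + np.sqrt(1.0 - rho**2) * eps
    )
    for cov, beta in spec.covariate_effects.items():
        col = {"age_years": age, "sex": sex, "handedness": handedness}[cov]
        target_score = target_score + beta * np.asarray(col, dtype=float)

    pheno = pd.DataFrame({
        "subject_id": [c.subject_id for c in subjects],
        "age_years": np.round(age, 2),
        "sex": sex,
        "handedness": handedness,
    })
    for score, (mu, sd) in SCORE_DISTRIBUTIONS.items():
        if score == spec.score_name:
            pheno[score] = target_score
        else:
            pheno[score] = mu + sd * rng.standard_normal(n)
    pheno["ran_items_per_sec"] = pheno["ran_items_per_sec"].clip(lower=0.2)
    return subjects, pheno


def write_cohort(
    subjects: list[WeightedConnectome],
    pheno: pd.DataFrame,
    out_dir: str | Path,
    spec: CohortSpec | None = None,
) -> Path:
    """Emit the on-disk cohort layout: one weights TSV and FA TSV per
    subject plus ``phenotypes.csv`` and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for c in subjects:
        netcore.save_connectome(
            c,
            out / f"{c.subject_id}_weights.tsv",
            (out / f"{c.subject_id}_fa.tsv") if c.fa is not None else None,
        )
    pheno.to_csv(out / "phenotypes.csv", index=False)
    if subjects:
        pivot = (netcore.LEFT_THALAMUS
                 if netcore.LEFT_THALAMUS in subjects[0].node_labels
                 else subjects[0].node_labels[0])
        reading = reading_set_for(subjects[0], pivot)
        (out / "reading_regions.txt").write_text("\n".join(reading) + "\n")
    if spec is not None:
        manifest = {k: getattr(spec, k) for k in (
            "n_subjects", "n_nodes", "planted_rho", "target_metric",
            "score_name", "score_mean", "score_sd", "network", "density",
            "n_hubs", "weight_jitter_sd", "seed")}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


# ---------------------------------------------------------------------------
# Closed-form toy graphs
# ---------------------------------------------------------------------------

def toy_fixture(name: str) -> ToyFixture:
    """Small graphs with hand-derivable metrics and routing costs."""
    W = 3.0  # uniform weight, supra-threshold
    if name == "triangle":
        labels = ("A", "B", "C")
        w = np.full((3, 3), W)
        np.fill_diagonal(w, 0)
        expected = {"cc": 1.0, "le": 1.0}
    elif name == "star5":
        labels = tuple("C12345")
        w = np.zeros((6, 6))
        w[0, 1:] = W
        w[1:, 0] = W
        expected = {"cc_center": 0.0, "le_center": 0.0}
    elif name == "path3":
        labels = ("A", "B", "C")
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = W
        w[1, 2] = w[2, 1] = W
        d = 1.0 / W
        expected = {"g_AC": 2 * d, "d_edge": d,
                    "cc_B": 0.0, "le_B": 0.0}
    elif name == "complete4":
        labels = ("A", "B", "C", "D")
        w = np.full((4, 4), W)
        np.fill_diagonal(w, 0)
        expected = {"cc": 1.0, "le": 1.0}
    elif name == "two_module_bridge":
        # triangle ABC — bridge — triangle DEF; bridge edge C–D
        labels = ("A", "B", "C", "D", "E", "F")
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
            w[i, j] = w[j, i] = W
        expected = {"bridge_nodes": ("C", "D")}
    elif name == "single_edge":
        labels = ("A", "B")
        w = np.array([[0.0, W], [W, 0.0]])
        expected = {"c_trans_flat": 1.0 / W, "c_info_flat": 0.0}
    else:
        raise ValueError(f"unknown toy fixture {name!r}")
    return ToyFixture(name, labels, w, expected)


TOY_FIXTURE_NAMES = ("triangle", "star5", "path3", "complete4",
                     "two_module_bridge", "single_edge")
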