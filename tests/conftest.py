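import numpy as np
import pytest

from thalroute import WeightedConnectome, threshold_edges


def random_connectome(n_nodes, density, seed, weight_hi=20, labels=None):
    """Small random symmetric integer-weight graph (may be disconnected);
    used where tests need arbitrary topology rather than the hub-core
    generator."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n_nodes, n_nodes))
    iu, ju = np.triu_indices(n_nodes, k=1)
    on = rng.random(iu.size) < density
    vals = rng.integers(3, weight_hi + 1, size=iu.size)
    w[iu[on], ju[on]] = vals[on]
    w[ju[on], iu[on]] = vals[on]
    if labels is None:
        labels = tuple(f"N{i}" for i in range(n_nodes))
    return WeightedConnectome(labels, w, subject_id=f"rand{seed}")


def random_connected_connectome(n_nodes, density, seed, weight_hi=20):
    """Random graph guaranteed connected by a spanning ring."""
    rng = np.random.default_rng(seed)
    c = random_connectome(n_nodes, density, seed, weight_hi)
    w = c.weights.copy()
    order = rng.permutation(n_nodes)
    for a, b in zip(order, np.roll(order, 1)):
        if w[a, b] == 0:
            v = rng.integers(3, weight_hi + 1)
            w[a, b] = w[b, a] = v
    return WeightedConnectome(c.node_labels, w, subject_id=c.subject_id)


@pytest.fixture(scope="session")
def small_thresholded():
    return threshold_edges(random_connected_connectome(10, 0.4, seed=7))
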