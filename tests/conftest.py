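import numpy as np
import pytest

from hyperbrain.classification import CVConfig
from hyperbrain.hypernet import HyperEdge, HyperNetwork
from hyperbrain.pipeline import build_cohort_networks
from hyperbrain.synthetic import SimulationConfig, simulate_cohort


def make_network(edge_node_sets, n_nodes):
    """HyperNetwork from explicit node sets (seed = smallest member)."""
    edges = [HyperEdge(nodes=frozenset(s), seed_roi=min(s), lambda_relative=0.5)
             for s in edge_node_sets]
    return HyperNetwork(n_nodes=n_nodes, edges=edges)


def random_hypergraph(rng, max_nodes=12, max_edges=8):
    """A random hypergraph with edges of size >= 2 (possibly none)."""
    n = int(rng.integers(3, max_nodes + 1))
    n_edges = int(rng.integers(0, max_edges + 1))
    seen = set()
    for _ in range(n_edges):
        size = int(rng.integers(2, min(n, 5) + 1))
        nodes = tuple(sorted(rng.choice(n, size=size, replace=False).tolist()))
        seen.add(nodes)
    return make_network(sorted(seen), n)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# Reduced CV settings used by the heavier end-to-end tests: fewer repeats
# and coarser hyper-parameter grids than the defaults, chosen for runtime.
def reduced_cv(seed, n_repeats=2):
    return CVConfig(n_folds=10, n_repeats=n_repeats, seed=seed,
                    alpha_grid=(0.0, 0.3, 0.5, 0.7, 1.0),
                    svm_cost_grid=(0.125, 1.0, 8.0), inner_folds=3)


_network_cache = {}


def cohort_and_networks(seed, effect_size, n_per_group=30, n_rois=20,
                        n_timepoints=120, n_perturbed=4):
    """Cohort + per-subject hyper-networks, cached across tests."""
    key = (seed, effect_size, n_per_group, n_rois, n_timepoints, n_perturbed)
    if key not in _network_cache:
        cfg = SimulationConfig(n_group0=n_per_group, n_group1=n_per_group,
                               n_rois=n_rois, n_timepoints=n_timepoints,
                               n_perturbed_rois=n_perturbed,
                               effect_size=effect_size, seed=seed)
        cohort = simulate_cohort(cfg)
        _network_cache[key] = (cohort, build_cohort_networks(cohort))
    return _network_cache[key]
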