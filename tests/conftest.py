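import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from restconn import CohortSpec, ThresholdedNetwork, fixture_graph, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def triangle_pendant():
    """Triangle a-b-c plus pendant d attached to a (binary)."""
    adj = np.zeros((4, 4))
    for a, b in [(0, 1), (0, 2), (1, 2), (0, 3)]:
        adj[a, b] = adj[b, a] = 1.0
    return ThresholdedNetwork(adj, density=1.0, mode="binary")


@pytest.fixture()
def two_cliques3():
    return fixture_graph("two_cliques", 3)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort for pipeline-level tests: 3 modules of 10 nodes."""
    return CohortSpec(
        n_per_group=(6, 6), n_nodes=30, n_timepoints=80, n_modules=3,
        effect_nodes=(12,), behavior_node=22, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study's default conditions (28/29, 90 nodes)."""
    return generate_cohort(CohortSpec(seed=41))
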