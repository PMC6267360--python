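import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import safetybn as sb
from safetybn.network import (BayesianNetwork, ConditionalProbabilityTable,
                              NodeSpec, uniform_cpt)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def accident_bn():
    """The fixed 10-node network with uniform CPTs."""
    return sb.build_accident_network()


@pytest.fixture(scope="session")
def ground_truth():
    """Default synthetic ground truth (reference attitude CPT installed)."""
    return sb.default_ground_truth()


@pytest.fixture(scope="session")
def recovery_truth():
    """Uniform-root variant used for parameter-recovery checks."""
    return sb.uniform_root_ground_truth()


def random_cpts(bn: BayesianNetwork, rng: np.random.Generator
                ) -> BayesianNetwork:
    """Replace every CPT with Dirichlet(1) rows."""
    new = bn.copy()
    for node in bn.nodes:
        spec = bn.nodes[node]
        rows = bn.parent_configurations(node)
        p = rng.dirichlet(np.ones(spec.n_states), size=len(rows))
        new.cpts[node] = ConditionalProbabilityTable(node, tuple(rows), p)
    return new


def random_network(rng: np.random.Generator, n_nodes: int
                   ) -> BayesianNetwork:
    """A random DAG of ternary nodes with Dirichlet CPTs."""
    names = [f"n{i}" for i in range(n_nodes)]
    states = ("a", "b", "c")
    nodes = {}
    for i, name in enumerate(names):
        k = int(rng.integers(0, min(i, 3) + 1))
        parents = tuple(rng.choice(names[:i], size=k, replace=False)) if k else ()
        nodes[name] = NodeSpec(name, states, parents)
    bn = BayesianNetwork(nodes)
    bn.cpts = {n: uniform_cpt(bn, n) for n in nodes}
    return random_cpts(bn, rng)


@pytest.fixture
def make_random_network():
    return random_network


@pytest.fixture
def make_random_cpts():
    return random_cpts
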