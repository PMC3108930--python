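import numpy as np
import pytest

from domainprio.net_kernels import DomainNetwork, diffusion_kernel, sg_kernel
from domainprio.profiles import AssociationSet, PhenotypeSimilarity
from domainprio.synthio import SyntheticScenario, simulate_scenario


@pytest.fixture(scope="session")
def toy_network():
    """Six domains: a 4-cycle a-b-c-d plus pendant e on a; f isolated."""
    return DomainNetwork(
        ["a", "b", "c", "d", "e", "f"],
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "e")],
    )


@pytest.fixture(scope="session")
def toy_assoc():
    return AssociationSet(
        [("a", "p1"), ("b", "p1"), ("c", "p2"), ("d", "p3"), ("e", "p4")]
    )


@pytest.fixture(scope="session")
def toy_similarity():
    rng = np.random.default_rng(0)
    ids = ["p1", "p2", "p3", "p4", "p5"]
    vals = rng.uniform(0.0, 1.0, size=(5, 5))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    return PhenotypeSimilarity(ids, vals)


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic study: 400 domains, 150 phenotypes, signal 0.9."""
    return simulate_scenario(SyntheticScenario(seed=20260))


@pytest.fixture(scope="session")
def scenario_dk(scenario):
    return diffusion_kernel(scenario.network, 0.05)


@pytest.fixture(scope="session")
def scenario_sg(scenario):
    return sg_kernel(scenario.network, 1.0)
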