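import numpy as np
import pytest

import pobench as pb

#: the ten latent toxicity profiles of the running 2x2 illustration
WORKED_PROFILES = np.array(
    [0.59, 0.01, 0.29, 0.28, 0.81, 0.26, 0.72, 0.31, 0.95, 0.11]
)


@pytest.fixture(scope="session")
def worked_profiles():
    return WORKED_PROFILES.copy()


@pytest.fixture(scope="session")
def worked_scenario():
    """2x2 scenario p = [[.10, .30], [.20, .40]], gamma = 0.20, n = 10."""
    return pb.load_scenario("worked_example")


@pytest.fixture(scope="session")
def orderings_2x2():
    return pb.enumerate_linear_extensions(pb.DoseGrid(2, 2))


@pytest.fixture(scope="session")
def worked_assignment(worked_scenario, orderings_2x2):
    return pb.build_assignments(worked_scenario.tox_probs, orderings_2x2)


@pytest.fixture(scope="session")
def paper_ordering_index(worked_assignment, worked_scenario):
    """Canonical index of the true ordering (d11->d21->d12->d22)."""
    idx = worked_assignment.true_ordering_indices(worked_scenario.tox_probs)
    assert len(idx) == 1
    return int(idx[0])
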