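import numpy as np
import pytest

from eldercea import fixtures


@pytest.fixture(scope="session")
def matrix():
    return fixtures.transition_matrix()


@pytest.fixture(scope="session")
def payoffs():
    return fixtures.payoff_table()


@pytest.fixture(scope="session")
def arms():
    return fixtures.trial_arms()


@pytest.fixture(scope="session")
def sheets():
    return fixtures.cost_sheets()


@pytest.fixture()
def all_mild():
    from eldercea.model_core import CohortDistribution

    return CohortDistribution.all_mild()
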