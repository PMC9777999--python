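import numpy as np
import pytest

from rbroc import elicitation, fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2022)


@pytest.fixture(scope="session")
def demo_counts():
    return fixtures.demo_discrete_counts()


@pytest.fixture(scope="session")
def demo_truth():
    return fixtures.demo_discrete_truth()


@pytest.fixture(scope="session")
def demo_summaries():
    return fixtures.demo_binormal_summaries()


@pytest.fixture(scope="session")
def demo_normal_gamma():
    """Elicited normal-gamma prior: means in (-5, 5), half-lengths (1, 10)."""
    return elicitation.elicit_normal_gamma(-5, 5, 1, 10, 0.99)


@pytest.fixture(scope="session")
def demo_prevalence_prior():
    """Elicited prevalence prior: w in [0.2, 0.6] with virtual certainty."""
    return elicitation.elicit_beta_prevalence(0.2, 0.6, 0.99)
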