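import pytest

from dimerbias import SyntheticSpec, generate_pair, mixing_fractions


@pytest.fixture(scope="session")
def one_to_three():
    """The 1:3 labeled:unlabeled mixing used in the solution experiments."""
    return mixing_fractions(1.0, 3.0)


@pytest.fixture()
def noise_free_pair():
    """Reference/mixed tables with p_A_true = 0.04 and no noise."""
    spec = SyntheticSpec(p_A_true=0.04, noise_cv=0.0, seed=11)
    return generate_pair(spec)
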