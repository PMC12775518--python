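import numpy as np
import pytest

from solenoidforge import MockOracleSuite, RepeatSpec, RepeatUnit, SolenoidClass


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hidden_target():
    return RepeatUnit("ADKLMW")


@pytest.fixture
def beta_spec(hidden_target):
    # min_plddt high enough that only the exact hidden unit clears the
    # gate on the surrogate landscape (worst model = 0.18 + 0.8 q).
    return RepeatSpec(
        repeat_length=len(hidden_target),
        num_repeats=4,
        target_class=SolenoidClass.BETA,
        min_plddt=0.97,
    )


@pytest.fixture
def mock_suite(hidden_target):
    return MockOracleSuite(hidden_target=hidden_target, target_class=SolenoidClass.BETA)
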