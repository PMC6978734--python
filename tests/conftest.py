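import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from hebbseq.transfer import PiecewiseLinearTF, PiecewiseNonlinearTF, SigmoidTF


@pytest.fixture(scope="session")
def pl_tf():
    return PiecewiseLinearTF()


@pytest.fixture(scope="session")
def all_tfs():
    return [SigmoidTF(), PiecewiseLinearTF(), PiecewiseNonlinearTF()]
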