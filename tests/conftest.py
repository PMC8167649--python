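import numpy as np
import pytest

from hrvt.synth import RampSpec, generate_ramp


@pytest.fixture(scope="session")
def default_ramp():
    """One seeded default-condition ramp shared across tests."""
    series, truth = generate_ramp(RampSpec(seed=7))
    return series, truth


@pytest.fixture(scope="session")
def short_ramp():
    """A 10-minute ramp, cheaper for pipeline plumbing tests."""
    spec = RampSpec(
        duration_s=600,
        hr_start=80,
        hr_end=190,
        hr_decline_start=130,
        hr_crossing=165,
        seed=11,
    )
    series, truth = generate_ramp(spec)
    return series, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
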