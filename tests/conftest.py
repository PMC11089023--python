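import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240512)


@pytest.fixture
def noiseless_phantom():
    from ecvrisk.synthetic import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=5))
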