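import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return random.Random(0)


@pytest.fixture
def dna_rng():
    r = random.Random(1234)

    def make(length, alphabet="ACGT"):
        return "".join(r.choice(alphabet) for _ in range(length))

    return make
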