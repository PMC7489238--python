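import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from promin import FrequencyVector, generate_proteome  # noqa: E402


@pytest.fixture(scope="session")
def uniform_background():
    """Medium synthetic proteome with uniform residue composition."""
    return generate_proteome(200, 150, FrequencyVector.uniform(), seed=1234)


@pytest.fixture(scope="session")
def small_background():
    return generate_proteome(40, 80, seed=99)
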