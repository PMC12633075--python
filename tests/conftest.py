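import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pseudomsa import AminoSequence, FixtureSpec, MockTranslator, generate_fixture_set
from pseudomsa.alphabets import AA_ALPHABET

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def query60(rng):
    residues = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=60))
    return AminoSequence(residues, id="q60")


@pytest.fixture()
def mock_backend():
    return MockTranslator(seed=11, identity_band=(0.3, 0.5), forward_noise=0.05)


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """The packaged synthetic fixture set, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = generate_fixture_set(7, FixtureSpec(), out)
    return out, manifest
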