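import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sangermix import SimSpec, divergent_pair, simulate_mixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


from helpers import make_chromatogram  # noqa: E402


@pytest.fixture
def toy_trace_factory():
    return make_chromatogram


@pytest.fixture(scope="session")
def clean_triple():
    """Noise-free, identity-warp (mixed, ref1, ref2) at omega = 0.3."""
    rng = np.random.default_rng(42)
    seq1, seq2 = divergent_pair(300, 25, rng)
    spec = SimSpec(noise_sd=0.0, spacing_jitter=0.0, seed=5)
    mixed, ref1, ref2 = simulate_mixture(seq1, seq2, 0.3, spec, spec, spec)
    return mixed, ref1, ref2


@pytest.fixture(scope="session")
def clean_pair_specs():
    """Sequences and the shared noise-free spec used by clean_triple."""
    rng = np.random.default_rng(42)
    seq1, seq2 = divergent_pair(300, 25, rng)
    return seq1, seq2, SimSpec(noise_sd=0.0, spacing_jitter=0.0, seed=5)
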