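import numpy as np
import pytest

from pulsedyn.synthdata import BenchmarkSpec, make_benchmark

BENCHMARK_LIFETIMES = (1.87, 34.8)


@pytest.fixture(scope="session")
def benchmark():
    """Noiseless sequential three-species benchmark matrix."""
    return make_benchmark(BenchmarkSpec())


@pytest.fixture(scope="session")
def noisy_benchmark():
    """10%-noise benchmark at a fixed seed."""
    return make_benchmark(BenchmarkSpec(noise_fraction=0.10, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
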