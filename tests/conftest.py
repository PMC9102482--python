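import numpy as np
import pytest

import myohmi as m


@pytest.fixture(scope="session")
def benchmark_segments():
    """The seeded 40-per-class labeled benchmark used across test modules."""
    return m.make_benchmark_segments(n_per_class=40, seed=42)


@pytest.fixture(scope="session")
def benchmark_fit(benchmark_segments):
    """Classifier fit on the benchmark with the default configuration."""
    return m.EmgClassifier.from_segments(benchmark_segments).fit(m.TrainConfig())


@pytest.fixture(scope="session")
def small_fit():
    """A quickly trained classifier for pipeline-level tests."""
    segs = m.make_benchmark_segments(n_per_class=15, seed=7)
    return m.EmgClassifier.from_segments(segs).fit(m.TrainConfig(epochs=800))


@pytest.fixture(scope="session")
def robot():
    return m.Manipulator()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
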