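import numpy as np
import pytest

from dsprefine.core import ScoreParams, load_score_matrix
from dsprefine.refine import AlignmentProvider, TreeProvider
from dsprefine.synth import SynthConfig, generate_dataset

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def params():
    return ScoreParams()


@pytest.fixture(scope="session")
def blosum45():
    return load_score_matrix("BLOSUM45")


@pytest.fixture(scope="session")
def benchmark():
    """Fully corrupted synthetic benchmark: 20 families, 10 species."""
    return generate_dataset(SynthConfig(seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def benchmark_provider(benchmark):
    return AlignmentProvider(benchmark.sequences)


@pytest.fixture(scope="session")
def split_only_benchmark():
    """Benchmark carrying only the false-split defects (merge targets)."""
    return generate_dataset(
        SynthConfig(
            seed=BENCHMARK_SEED,
            boundary_jitter=0,
            unsplit_fraction=0.0,
            pool_fraction=0.0,
        )
    )


@pytest.fixture()
def tree_provider():
    return TreeProvider()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)
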