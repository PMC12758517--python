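import numpy as np
import pytest

from gonadnet.pipeline import PipelineParams, run_pipeline
from gonadnet.simulate import SimConfig, null_config, simulate_multiome


@pytest.fixture(scope="session")
def default_dataset():
    """Default study-condition dataset: ~2000 cells, 500 genes, 2000 peaks."""
    return simulate_multiome(SimConfig(seed=0))


@pytest.fixture(scope="session")
def pipeline_results(default_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(default_dataset, out, PipelineParams(seed=0))


@pytest.fixture(scope="session")
def null_dataset():
    """All planted effects zero: 200 genes, 500 peaks, 2 x 200 cells."""
    return simulate_multiome(null_config(seed=0))


@pytest.fixture(scope="session")
def small_config():
    """A fast configuration for end-to-end determinism/smoke tests."""
    return SimConfig(seed=0, n_cells_per_group=15, n_genes=80, n_peaks=250,
                     genome_length_bp=3_000_000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
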