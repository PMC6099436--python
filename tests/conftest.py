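import pytest

from phytoscreen.pipeline import PipelineConfig, run_pipeline
from phytoscreen.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """Default synthetic cress dataset (seed 42) written to disk."""
    d = tmp_path_factory.mktemp("synthetic")
    generate_dataset(SimConfig(seed=42), out_dir=d)
    return d


@pytest.fixture(scope="session")
def dataset():
    """In-memory default dataset with its truth manifest."""
    return generate_dataset(SimConfig(seed=42))


@pytest.fixture(scope="session")
def pipeline_result(dataset_dir):
    """Full pipeline run on the default dataset with default config."""
    return run_pipeline(PipelineConfig(), dataset_dir)
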