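import numpy as np
import pytest

from wheatrisk.indicators import INDICATOR_NAMES, compute_indicators
from wheatrisk.pipeline import PipelineConfig, run_pipeline
from wheatrisk.synthetic import GeneratorConfig, consumption_table, generate_dataset
from wheatrisk.toxicology import load_toxicology

TEST_MASTER_SEED = 0


@pytest.fixture(scope="session")
def tox():
    return load_toxicology()


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic surveillance dataset (the study conditions)."""
    batch, profiles = generate_dataset(GeneratorConfig(seed=TEST_MASTER_SEED))
    return batch, profiles


@pytest.fixture(scope="session")
def default_indicators(default_dataset, tox):
    batch, profiles = default_dataset
    return compute_indicators(batch, consumption_table(profiles), tox)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default pipeline run shared by the end-to-end tests."""
    return run_pipeline(PipelineConfig().with_master_seed(TEST_MASTER_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def indicator_names():
    return list(INDICATOR_NAMES)
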