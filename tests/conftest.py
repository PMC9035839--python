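import numpy as np
import pytest

from nnan.attention_predictor import TrainConfig
from nnan.drug_similarity import fingerprint_similarity_matrix
from nnan.evaluation import PipelineConfig
from nnan.microbe_similarity import microbe_similarity_matrix
from nnan.synthetic_data import SynthConfig, generate, worked_toy


@pytest.fixture(scope="session")
def toy():
    """Frozen 5-drug / 3-microbe instance used as the cross-module oracle."""
    return worked_toy()


@pytest.fixture(scope="session")
def small_synth():
    """Reduced planted-cluster dataset for fast pipeline tests."""
    return generate(
        SynthConfig(
            n_drug_clusters=3,
            drugs_per_cluster=6,
            n_microbe_clusters=2,
            microbes_per_cluster=4,
            seq_len=120,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_synth_sims(small_synth):
    dsim = fingerprint_similarity_matrix(
        small_synth.drug_ids, small_synth.fingerprints
    )
    msim = microbe_similarity_matrix(small_synth.microbes)
    return dsim, msim


@pytest.fixture
def fast_pipeline_config():
    return PipelineConfig(
        train=TrainConfig(epochs=120, seed=0), negative_ratio="all", seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
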