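import numpy as np
import pytest

from danemda.autoencoder import AutoencoderSpec
from danemda.predictor import PipelineConfig
from danemda.synthdata import SyntheticConfig, generate_synthetic_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-partition dataset for fast end-to-end tests."""
    cfg = SyntheticConfig(
        n_mirnas=40, n_diseases=20, n_groups=4, p_in=0.6, p_out=0.02,
        seq_len=22, motif_len=8, mutation_rate=0.1, dag_branching=3, seed=11,
    )
    return generate_synthetic_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default configuration (the acceptance-scale dataset)."""
    return generate_synthetic_dataset(SyntheticConfig())


@pytest.fixture
def fast_ae_spec():
    """Cheap auto-encoder spec for pipeline tests on tiny inputs."""
    return AutoencoderSpec(hidden_dims=(24, 8), epochs_pretrain=10,
                           epochs_finetune=25, seed=5)


@pytest.fixture
def fast_config(fast_ae_spec):
    return PipelineConfig(autoencoder=fast_ae_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
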