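import numpy as np
import pytest

from synergraph import ModelConfig, SyntheticSpec, make_synthetic_study


@pytest.fixture(scope="session")
def study():
    """The reference desk-scale synthetic study (20 drugs, 2 cell lines)."""
    return make_synthetic_study(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def noiseless_study():
    """Deterministic-label study: no noise, every pair observed."""
    return make_synthetic_study(SyntheticSpec(sigma=0.0, density=1.0, seed=7))


@pytest.fixture()
def compact_config():
    """Small, fast model configuration used in training tests."""
    return ModelConfig(d=16, latent=32, modality_hidden=64, pred_hidden=(64,),
                       mol_layers=(32, 32), epochs=30, batch_size=None)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
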