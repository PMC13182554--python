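import numpy as np
import pytest

from odorstrength import featurize, synthetic


@pytest.fixture(scope="session")
def small_smiles():
    """60 grammar molecules shared across tests (session-cached)."""
    cfg = synthetic.GeneratorConfig(n_molecules=60, seed=7)
    return synthetic.generate_molecules(cfg)


@pytest.fixture(scope="session")
def small_descriptors(small_smiles):
    return featurize.descriptors(small_smiles)


@pytest.fixture(scope="session")
def labeled_dataset():
    """Noiseless-labels dataset of 300 molecules for model tests."""
    cfg = synthetic.GeneratorConfig(n_molecules=300, seed=11, noise_sd=0.0, label_noise=0.0)
    smiles = synthetic.generate_molecules(cfg)
    return synthetic.assign_labels(smiles, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
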