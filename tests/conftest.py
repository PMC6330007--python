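import numpy as np
import pytest

from vqtlkit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ideal_dataset():
    """A moderately heteroskedastic discrete-genotype dataset."""
    cfg = SimulationConfig(n=300, pi_maf=0.3, beta0=1.0, beta=0.5,
                           log_alpha=0.3, seed=77)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_classifier():
    """A reduced trait-distribution classifier shared across tests."""
    from vqtlkit.classify import build_training_set, default_bank, train_classifier

    bank = default_bank()
    X, labels = build_training_set(bank, samples_per_cell=4, n=100,
                                   ref_size=60, seed=9)
    model = train_classifier(X, labels, folds=2, seed=9, bank=bank)
    return bank, model
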