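import numpy as np
import pytest

from zsdecode import (MultiViewDataset, MultiViewEmbedding, sample_dataset,
                      sample_ground_truth)


@pytest.fixture(scope="session")
def recovery_truth():
    """Ground truth at the standard recovery conditions: 60/40/20 features,
    5 latent components of which the last is inactive in every view, high SNR."""
    return sample_ground_truth(seed=11, snr=10.0, zero_latent_columns=(4,))


@pytest.fixture(scope="session")
def recovery_bundle(recovery_truth):
    """N=300 paired source samples, M=104 additional target samples."""
    return sample_dataset(recovery_truth, n_per_source_category=15,
                          m_add_per_target_category=13,
                          n_test_per_target_category=5, seed=11)


@pytest.fixture(scope="session")
def recovery_fit(recovery_bundle):
    model = MultiViewEmbedding(recovery_bundle.dataset, latent_dim=5, seed=7)
    return model.fit()


@pytest.fixture()
def tiny_dataset():
    """Deterministic 3-view dataset small enough for exhaustive checks."""
    rng = np.random.default_rng(0)
    n = 12
    z = rng.standard_normal((2, n))
    return MultiViewDataset(
        brain=rng.standard_normal((6, 2)) @ z + 0.05 * rng.standard_normal((6, n)),
        visual=rng.standard_normal((4, 2)) @ z + 0.05 * rng.standard_normal((4, n)),
        semantic=rng.standard_normal((3, 2)) @ z + 0.05 * rng.standard_normal((3, n)),
        paired_labels=[f"c{i % 4}" for i in range(n)],
    )
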