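import numpy as np
import pytest

import spose2afc as s


@pytest.fixture(scope="session")
def truth_small():
    """12 classes x 3 exemplars, 4 true dimensions."""
    return s.make_ground_truth(n_classes=12, exemplars_per_class=3, k_dims=4,
                               sparsity=0.5, seed=7)


@pytest.fixture(scope="session")
def sim_small(truth_small):
    return s.simulate_trials(truth_small, n_trials=40_000, lapse_rate=0.05, seed=11)


@pytest.fixture(scope="session")
def classes_small(truth_small):
    return truth_small.images.set_index("image_id")["class_label"]


@pytest.fixture(scope="session")
def fit_small(truth_small, sim_small):
    cfg = s.FitConfig(n_init_dims=8, lam=0.3, max_epochs=60, patience=15, seed=3)
    return s.fit_embedding(sim_small.trials, truth_small.images, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def random_embedding(n, k, seed=0, scale=1.0):
    r = np.random.default_rng(seed)
    return s.Embedding(scale * np.abs(r.standard_normal((n, k))),
                       [f"im{i}" for i in range(n)])
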