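import numpy as np
import pytest

import connparc as cp


@pytest.fixture(scope="session")
def small_cohort():
    """Small high-signal synthetic cohort shared by read-only tests."""
    cfg = cp.SyntheticConfig(
        n_participants=8,
        n_seed_voxels=40,
        n_targets=80,
        k_true=4,
        fingerprint_scale=5.0,
        noise_scale=1.0,
        rng_seed=11,
    )
    truth = cp.make_planted_labels(cfg)
    matrices = cp.simulate_group(cfg, truth)
    return cfg, truth, matrices


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    _, _, matrices = small_cohort
    return cp.participant_profiles(matrices)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
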