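import numpy as np
import pytest

import fedgap as fg


@pytest.fixture(scope="session")
def tiny_spec():
    """Fast low-dimensional cohort spec for structural tests."""
    return fg.UKB_LIKE.with_(n_subjects=30, feature_dim=16, seed=123, disease_fraction=0.2)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return fg.generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def noiseless_spec():
    """All noise terms zero, purely linear age signal."""
    return fg.UKB_LIKE.with_(
        n_subjects=600,
        feature_dim=1024,
        seed=7,
        latent_sd=0.0,
        site_sd=0.0,
        eye_sd=0.0,
        noise_sd=0.0,
        nonlinearity_coef=0.0,
        disease_fraction=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_spec):
    return fg.generate_cohort(noiseless_spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Medium-size default-noise cohort for training behaviour tests."""
    return fg.generate_cohort(fg.UKB_LIKE.with_(n_subjects=700, feature_dim=128, seed=42))


@pytest.fixture(scope="session")
def small_split(small_cohort):
    clients = fg.build_network(small_cohort)
    plan = fg.SplitPlan(n_train=200, n_val=150, seed=9)
    return fg.monte_carlo_split(clients, plan, 0)
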