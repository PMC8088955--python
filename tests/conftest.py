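import numpy as np
import pytest

from eaccd import EACCDModel, generate_cases, planted_tiers_config


@pytest.fixture(scope="session")
def tier_data():
    """Small planted 3-tier case listing shared across tests."""
    cfg = planted_tiers_config(n_combinations=12, k_true=3, hazard_ratio=4.0,
                               cohort_size=150, seed=42)
    cases, truth = generate_cases(cfg)
    return cases, truth


@pytest.fixture(scope="session")
def tier_fit(tier_data):
    cases, truth = tier_data
    model = EACCDModel(cases, active_factors=("T", "N", "M"), min_cases=50)
    return model, model.fit(runs=100, seed=42), truth


def random_censored_cohort(rng, n, scale=30.0, censor_frac=0.3):
    t = np.ceil(rng.exponential(scale, n))
    c = np.ceil(rng.exponential(scale / censor_frac, n))
    obs = np.minimum(t, c)
    return obs, (t <= c).astype(int)
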