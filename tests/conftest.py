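import numpy as np
import pytest

from dynrisk import (
    SurvivalNetConfig,
    apply_eligibility,
    default_simulation_config,
    simulate_cohort,
    split_dataset,
    train,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Default study conditions at reduced size, eligibility applied."""
    cfg = default_simulation_config(n_participants=1500, seed=42)
    cohort, _ = apply_eligibility(simulate_cohort(cfg))
    return cohort


@pytest.fixture(scope="session")
def small_splits(small_cohort):
    splits = split_dataset(small_cohort, (3, 1, 1), seed=7)
    return {
        name: small_cohort.subset(splits.loc[splits["split"] == name, "id"])
        for name in ("train", "tune", "test")
    }


@pytest.fixture(scope="session")
def tiny_dynamic_model(small_splits):
    cfg = SurvivalNetConfig(mode="dynamic", rnn_hidden=16, fc_hidden=(16,), max_epochs=15, seed=3)
    return train(cfg, small_splits["train"], small_splits["tune"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
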