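import numpy as np
import pytest
from hypothesis import settings

from diadem import ModelConfig, Policy, generate_cohort, run_comparison

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def cfg() -> ModelConfig:
    return ModelConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def four_policy_run():
    """One moderate four-policy comparison shared by direction-of-effect
    and reconciliation tests (4,000 patients, common random numbers)."""
    cfg = ModelConfig()
    cfg.cohort.n_patients = 4_000
    cfg.cohort.seed = 7
    cohort = generate_cohort(cfg.cohort)
    policies = [Policy.from_id(p) for p in ("CP", "P1", "P2", "P3")]
    results = run_comparison(cohort, policies, cfg, seed=7)
    return cfg, results
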