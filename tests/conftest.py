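import pandas as pd
import pytest

from immflow.synthetic import SimConfig, cohort_frames, generate_cohort, planted_truth


@pytest.fixture(scope="session")
def default_cohort():
    """~200-sample cohort with the default study structure (fixed seed)."""
    cfg = SimConfig(n_controls=100, n_trauma=35, seed=1)
    subjects, panels = cohort_frames(cfg)
    return cfg, subjects, panels


@pytest.fixture(scope="session")
def default_truth(default_cohort):
    cfg, _, _ = default_cohort
    return pd.Series(planted_truth(cfg))


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_controls=20, n_trauma=10, seed=7)
    records, panels = generate_cohort(cfg)
    return cfg, records, panels
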