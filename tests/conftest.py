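"""Shared fixtures: small synthetic cohorts generated at test time."""

import warnings

import pytest

from srres import SimConfig, generate_cohort
from srres.synth import null_config

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size cohort under the default generating model."""
    cfg = SimConfig(n_participants=300, seed=42)
    baseline, weekly, truth = generate_cohort(cfg)
    return cfg, baseline, weekly, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Global-null cohort: no effects, no attrition, continuous symptoms."""
    cfg = null_config(300, seed=7)
    baseline, weekly, truth = generate_cohort(cfg)
    return cfg, baseline, weekly, truth
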