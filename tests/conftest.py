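"""Shared fixtures: small synthetic records and one analysed cohort member."""

import numpy as np
import pytest

from gaitcmc import config_for_group, generate_record
from gaitcmc.pipeline import AnalysisConfig, analyze_record


@pytest.fixture(scope="session")
def young_record():
    """A 2-minute coupled record of the young preset (about 107 epochs)."""
    cfg = config_for_group("young", duration_s=120.0, seed=42)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def young_analysis(young_record):
    """Full single-record analysis with maps kept, shared across test modules."""
    record, _ = young_record
    cfg = AnalysisConfig(min_heel_strikes=50)
    return analyze_record(record, "young-42", "young", "treadmill", cfg, keep_maps=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
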