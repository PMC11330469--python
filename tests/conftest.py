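"""Shared fixtures: one small cohort reused by the cheap unit tests."""

import numpy as np
import pytest

from radiofusion import synthetic as syn
from radiofusion import radiomics as rad


@pytest.fixture(scope="session")
def small_cohort():
    """24 subjects at the default 32^3 — enough for stratified 5-fold splits."""
    cfg = syn.CohortConfig(n_subjects=24, seed=123)
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return rad.feature_table(small_cohort, bin_width=0.25)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return syn.labels_of(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
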