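"""Shared fixtures: small synthetic eyes and record-level cohorts."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from drusensf import faf_mpod, normative
from drusensf.datatypes import TEST_TYPES
from drusensf.structure_function import log_transform_predictors
from drusensf.synthetic_data import (
    SimConfig,
    simulate_eye,
    simulate_location_records,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Coarse imaging geometry for fast rendering tests."""
    return SimConfig(
        px_per_deg=8.0, map_field_deg=20.0, random_seed=5, faf_noise=5.0
    )


@pytest.fixture(scope="session")
def drusen_eye(small_config):
    rng = np.random.default_rng(42)
    return simulate_eye(small_config, rng, "drusen", "D000", with_volume=True)


@pytest.fixture(scope="session")
def healthy_eye(small_config):
    rng = np.random.default_rng(43)
    return simulate_eye(small_config, rng, "healthy", "H000",
                        with_volume=True)


@pytest.fixture(scope="session")
def cohort_records():
    """Full-scale record-level cohort with sensitivity losses attached."""
    cfg = SimConfig(random_seed=7)
    rec = faf_mpod.compensate_records(simulate_location_records(cfg))
    healthy = rec[rec["cohort"] == "healthy"]
    models = {t: normative.fit_normative(healthy, t) for t in TEST_TYPES}
    drusen = log_transform_predictors(
        normative.apply_normative(rec[rec["cohort"] == "drusen"], models)
    )
    return cfg, healthy, drusen
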