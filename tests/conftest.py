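"""Shared fixtures. The expensive audio synthesis/feature extraction and the
simulated-cohort setup are built once per session and reused."""

from __future__ import annotations

import pytest

from timbrecolor.features import extract_features
from timbrecolor.scoring import Grade
from timbrecolor.simulate import (
    build_manifest,
    calibrate_jitter,
    make_cohort,
    simulate_responses,
    stimulus_features,
)
from timbrecolor.stimuli import PRESETS, partial_reduction_series

STIMULUS_SEED = 1
COHORT_SEED = 7
MORPH_PAIRS = (("piano", "flute"), ("flute", "piano"))


@pytest.fixture(scope="session")
def preset_series():
    """k = 0..10 partial-reduction series per preset, loudness-matched."""
    return {name: partial_reduction_series(spec, seed=STIMULUS_SEED) for name, spec in PRESETS.items()}


@pytest.fixture(scope="session")
def preset_features(preset_series):
    return {name: [extract_features(a) for a in series] for name, series in preset_series.items()}


@pytest.fixture(scope="session")
def manifest():
    return build_manifest(morph_pairs=MORPH_PAIRS)


@pytest.fixture(scope="session")
def features_table(manifest):
    return stimulus_features(manifest, seed=STIMULUS_SEED)


@pytest.fixture(scope="session")
def cohort():
    sigma_poor = calibrate_jitter(32.0, seed=COHORT_SEED)
    return make_cohort(seed=COHORT_SEED, poor_sigma=sigma_poor)


@pytest.fixture(scope="session")
def responses(cohort, manifest, features_table):
    return simulate_responses(cohort, manifest, features_table, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def synesthete_ids(cohort):
    return [p.subject_id for p in cohort if p.target_grade is not Grade.POOR]
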