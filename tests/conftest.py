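"""Shared fixtures: small synthetic datasets and regions, built once."""

from __future__ import annotations

import numpy as np
import pytest

from walkaudit.features import PRIMITIVE_FEATURES
from walkaudit.geosim import (
    RegionConfig,
    plant_prevalences,
    sample_participants,
    simulate_region,
)
from walkaudit.scenes import generate_scene_dataset


@pytest.fixture(scope="session")
def clean_scenes():
    """120 clean scenes (no distractors), balanced prevalence."""
    prev = {f: 0.5 for f in PRIMITIVE_FEATURES}
    return generate_scene_dataset(120, prev, distractor_rate=0.0, seed=2024)


@pytest.fixture(scope="session")
def small_region():
    """9x9 grid, 3x3 block groups: large enough for buffers, fast."""
    return simulate_region(RegionConfig(grid_rows=9, grid_cols=9, bg_rows=3, bg_cols=3), seed=11)


@pytest.fixture(scope="session")
def small_truth(small_region):
    # moderate baseline rates: a 9x9 region is too small for the rare
    # features' default rates to show any spread across buffers
    rates = {f: r for f, r in zip(PRIMITIVE_FEATURES, (0.7, 0.4, 0.35, 0.25, 0.3, 0.3, 0.2, 0.45))}
    return plant_prevalences(small_region, baseline_rates=rates, seed=12)


@pytest.fixture(scope="session")
def small_participants(small_region):
    return sample_participants(small_region, 40, seed=13)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
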