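"""Shared fixtures: a small seeded synthetic cohort, tiled once per session."""

from __future__ import annotations

import numpy as np
import pytest

from sirmil.pipeline import CohortData, prepare_cohort
from sirmil.synthdata import SynthConfig


@pytest.fixture(scope="session")
def small_synth_cfg() -> SynthConfig:
    """Ten slides, balanced classes, default colours, no artifacts."""
    return SynthConfig(n_slides=10, class_balance=0.5, tile_px=64, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_synth_cfg, tmp_path_factory) -> CohortData:
    out = tmp_path_factory.mktemp("cohort")
    return prepare_cohort(small_synth_cfg, out, resize_px=32)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
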