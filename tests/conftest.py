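"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from hrvfatigue.synthetic import (
    FATIGUE_PROFILE,
    NONFATIGUE_PROFILE,
    generate_rr_tachogram,
)
from hrvfatigue.types import RRSeries


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def constant_rr() -> RRSeries:
    return RRSeries(intervals=np.full(50, 800.0))


@pytest.fixture
def synthetic_rr() -> RRSeries:
    """One realistic 5-min rested-state tachogram (fixed seed)."""
    from dataclasses import replace

    return generate_rr_tachogram(replace(NONFATIGUE_PROFILE, seed=7))


@pytest.fixture
def fatigue_rr() -> RRSeries:
    from dataclasses import replace

    return generate_rr_tachogram(replace(FATIGUE_PROFILE, seed=7))


def random_rr(rng: np.random.Generator, n: int = 60) -> RRSeries:
    """Physiological-range random tachogram for property tests."""
    return RRSeries(intervals=rng.uniform(600.0, 1000.0, size=n))
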