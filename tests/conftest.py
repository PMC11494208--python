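"""Shared fixtures: simulated studies generated once per test session.

The drifting study applies graded heterogeneous preferred-direction
rotation (0 -> 90 deg across eight sessions) with modulation depths
shrinking to 70%, against a fixed decoder trained on day-0 calibration;
the stationary study re-runs the same population with zero drift.
"""

from __future__ import annotations

import numpy as np
import pytest

from mindful import (
    DriftEntry,
    DriftSchedule,
    MindfulScorer,
    PopulationSpec,
    generate_study,
    graded_drift_schedule,
    simulate_session,
    stationary_schedule,
)
from mindful.features import rolling_zscore

STUDY_DAYS = [0, 7, 14, 21, 28, 35, 42, 49]


@pytest.fixture(scope="session")
def population():
    return PopulationSpec.random(rng=7)


@pytest.fixture(scope="session")
def drifting_study(population):
    """(sessions, truth, decoder) under graded per-channel PD rotation."""
    schedule = graded_drift_schedule(STUDY_DAYS, max_rotation_deg=90.0, rng=7)
    return generate_study(population, schedule, seed=7)


@pytest.fixture(scope="session")
def stationary_study(population):
    """(sessions, truth, decoder) with zero drift, same population."""
    return generate_study(population, stationary_schedule(STUDY_DAYS), seed=8)


@pytest.fixture(scope="session")
def fitted_scorer(drifting_study):
    sessions, _, _ = drifting_study
    return MindfulScorer().fit(sessions)


@pytest.fixture(scope="session")
def drifting_windows(fitted_scorer, drifting_study):
    sessions, _, _ = drifting_study
    return fitted_scorer.transform(sessions)


@pytest.fixture(scope="session")
def drifting_zscores(drifting_study):
    sessions, _, _ = drifting_study
    return [
        rolling_zscore(s.features, s.bin_width, s.block_id)[0] for s in sessions
    ]


@pytest.fixture(scope="session")
def small_session(population):
    """One quick stationary closed-loop session for unit tests."""
    sessions, _, _ = generate_study(
        population,
        stationary_schedule([0]),
        trials_per_session=30,
        seed=3,
    )
    return sessions[0]
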