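"""Shared fixtures: small synthetic sessions reused across test modules.

Session-scoped so the expensive render/preprocess work is amortized.
Sizes are deliberately small (16-32 px, 60-90 s phases): the analysis
statistics under test do not depend on image resolution, and the phase
durations keep a full 60 s analysis window inside every phase.
"""
from __future__ import annotations

import numpy as np
import pytest

from duobrain.core import PhaseSchedule
from duobrain.preprocess import preprocess_session
from duobrain.synthetic import SessionParams, simulate_session


@pytest.fixture(scope="session")
def short_schedule() -> PhaseSchedule:
    return PhaseSchedule.from_durations(60.0, 10.0)


@pytest.fixture(scope="session")
def coupled_session(short_schedule):
    """One strongly coupled open-condition session at 32 px, rendered
    and preprocessed, with its ground truth."""
    params = SessionParams(
        schedule=short_schedule, image_size=32, seed=11, coupling=0.8
    )
    session, truth = simulate_session(params)
    processed = preprocess_session(session)
    return params, session, truth, processed


@pytest.fixture(scope="session")
def tiny_session(short_schedule):
    """A 16 px session for I/O and pipeline plumbing tests."""
    params = SessionParams(
        schedule=short_schedule, image_size=16, seed=5, coupling=0.5
    )
    session, truth = simulate_session(params)
    return params, session, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
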