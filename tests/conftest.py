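"""Shared fixtures: small simulated movies run once per session."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from sulfodiv import (
    DELTA_CDVB1,
    MW001,
    RunConfig,
    detect_division_events,
    link_tracks,
    simulate_movie,
)
from sulfodiv.pipeline import measure_movie

logging.getLogger("sulfodiv").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def mw001_noiseless():
    """Noiseless, drift-free MW001 field with several divisions, fully
    measured and tracked: the reference for exactness checks."""
    movie, truth = simulate_movie(
        MW001, n_cells=12, n_frames=50, frame_interval_s=30.0, seed=2,
        field_shape=(200, 200), noise=False, drift_step_sd_px=0.0,
    )
    cfg = RunConfig(preset="MW001", noise=False, drift_step_sd_px=0.0)
    observations = measure_movie(movie, cfg)
    tracks = link_tracks(observations)
    events = detect_division_events(tracks, movie.frame_interval_s)
    return {
        "movie": movie,
        "truth": truth,
        "observations": observations,
        "tracks": tracks,
        "events": events,
    }


@pytest.fixture(scope="session")
def cdvb1_noisy():
    """Noisy, drifting ΔcdvB1 field (membrane + DNA) through the full
    measurement chain after registration."""
    from sulfodiv import register_stack

    movie, truth = simulate_movie(
        DELTA_CDVB1, n_cells=40, n_frames=60, frame_interval_s=30.0, seed=5,
        field_shape=(300, 300), noise=True, drift_step_sd_px=0.5,
    )
    registered, trace = register_stack(movie, 0)
    cfg = RunConfig(preset="dCdvB1")
    observations = measure_movie(registered, cfg)
    tracks = link_tracks(observations)
    events = detect_division_events(tracks, movie.frame_interval_s)
    return {
        "movie": movie,
        "truth": truth,
        "registered": registered,
        "trace": trace,
        "observations": observations,
        "tracks": tracks,
        "events": events,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
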