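"""Shared fixtures: small simulated datasets and file fixtures.

Everything is generated programmatically at test time with fixed seeds;
nothing is loaded from disk except files the tests themselves write.
"""

from __future__ import annotations

import numpy as np
import pytest

from sptkin import (
    TrackSimParams,
    simulate_tracks,
)
from sptkin.tracks import Track, TrackSet, filter_tracks


@pytest.fixture(scope="session")
def single_state_tracks() -> TrackSet:
    """3000 pure-Brownian tracks at D = 0.1 µm²/s, no localization error."""
    params = TrackSimParams(
        diffusion_constants=(0.1,),
        fractions=(1.0,),
        n_tracks=3000,
        localization_sigma=0.0,
        seed=42,
    )
    return filter_tracks(simulate_tracks(params), min_length=5, bleach_cutoff_frame=0)


@pytest.fixture(scope="session")
def two_state_tracks() -> TrackSet:
    """Well-separated two-state mixture (D ratio 100), equal occupancy."""
    params = TrackSimParams(
        diffusion_constants=(1.0, 0.01),
        fractions=(0.5, 0.5),
        n_tracks=2000,
        localization_sigma=0.0,
        seed=7,
    )
    return filter_tracks(simulate_tracks(params), min_length=5, bleach_cutoff_frame=0)


@pytest.fixture
def straight_track() -> Track:
    """Deterministic straight-line track: step 0.1 µm per frame in x."""
    n = 12
    return Track(
        track_id=0,
        frames=np.arange(n),
        x=0.1 * np.arange(n, dtype=float),
        y=np.zeros(n),
    )


def make_tracks_csv(path, tracks: list[tuple[int, int]]) -> int:
    """Write a track CSV with given (track_id, length) pairs; returns rows."""
    lines = ["track_id,frame,x_um,y_um"]
    total = 0
    for tid, length in tracks:
        for i in range(length):
            lines.append(f"{tid},{i},{0.01 * i:.6f},{0.02 * i:.6f}")
            total += 1
    path.write_text("\n".join(lines) + "\n")
    return total
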