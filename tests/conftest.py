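"""Shared fixtures: tiny recordings, noiseless profiles, synthetic datasets."""

from dataclasses import replace

import numpy as np
import pytest

from oculofatigue.io_gaze import GazeRecording, ScreenGeometry, SessionMeta
from oculofatigue.synthgen import (
    generate_dataset,
    sample_participant_profile,
)

FS = 360.0


@pytest.fixture
def geometry() -> ScreenGeometry:
    return ScreenGeometry(viewing_distance_cm=58.0,
                          screen_width_cm=27.8, screen_height_cm=22.4)


@pytest.fixture
def still_recording(geometry) -> GazeRecording:
    """Five seconds of perfectly still gaze, pupil 3.5 mm."""
    n = int(5 * FS)
    t = np.arange(n) / FS
    return GazeRecording(
        timestamps=t,
        gaze_xy=np.zeros((n, 2)),
        pupil_mm=np.full(n, 3.5),
        geometry=geometry,
    )


def make_recording(pupil, geometry, xy=None, fs=FS) -> GazeRecording:
    pupil = np.asarray(pupil, dtype=float)
    n = pupil.size
    t = np.arange(n) / fs
    if xy is None:
        xy = np.zeros((n, 2))
    return GazeRecording(timestamps=t, gaze_xy=np.asarray(xy, dtype=float),
                         pupil_mm=pupil, geometry=geometry)


@pytest.fixture
def noiseless_profile():
    """A participant profile with every noise source switched off."""
    prof = sample_participant_profile(seed=11)
    return replace(prof, gaze_noise_deg=0.0, pupil_noise_mm=0.0,
                   peak_velocity_noise=0.0)


@pytest.fixture
def small_dataset():
    """Fast-path dataset small enough for model unit tests."""
    dataset, _ = generate_dataset(n_participants=6, n_segments=4, seed=42)
    return dataset


@pytest.fixture
def meta() -> SessionMeta:
    return SessionMeta(participant_id="P001", age=27.0, sex="F",
                       mode="automatic", kss_by_segment=[3] * 9)


def separable_dataset(n_participants=4, n_segments=6, seed=0):
    """Dataset whose BF feature perfectly separates the classes."""
    import pandas as pd
    from oculofatigue.io_gaze import LabeledDataset

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        for s in range(n_segments):
            fatigued = s >= n_segments // 2
            rows.append({
                "participant_id": f"P{i}", "segment_index": s + 1,
                "BF": (1.0 if fatigued else 0.0) + rng.normal(0, 0.01),
                "SF": rng.normal(2.0, 0.1),
                "age": 25.0, "sex": "F",
                "kss": 7 if fatigued else 2,
            })
    return LabeledDataset(pd.DataFrame(rows))
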