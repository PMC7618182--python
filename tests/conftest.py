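"""Shared fixtures: small deterministic datasets for fast tests.

``sinusoid_frames`` is the 2-class training fixture (300 frames of 500
samples; class 1 = 1 Hz tone, class 2 = 3 Hz tone, both with random phase,
amplitude jitter and additive noise, spread over 10 pseudo-patients).  It
is cheap to learn yet has class-conditional structure, so the GAN training
and evaluation tests run in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from ppgaug import FrameSet, default_profiles, frame_recordings, generate_cohort


def make_sinusoid_frames(
    n_per_class: int = 150, frame_len: int = 500, fs: float = 100.0, seed: int = 0
) -> FrameSet:
    rng = np.random.default_rng(seed)
    t = np.arange(frame_len) / fs
    frames, labels, pids = [], [], []
    for cls, freq in ((1, 1.0), (2, 3.0)):
        for i in range(n_per_class):
            phase = rng.uniform(0.0, 2 * np.pi)
            amp = rng.uniform(0.8, 1.2)
            x = amp * np.sin(2 * np.pi * freq * t + phase)
            x += 0.05 * rng.standard_normal(frame_len)
            frames.append(x)
            labels.append(cls)
            pids.append(f"p{i % 10}")
    return FrameSet(np.stack(frames), np.array(labels), np.array(pids), fs, frame_len / fs)


@pytest.fixture(scope="session")
def sinusoid_frames() -> FrameSet:
    return make_sinusoid_frames()


@pytest.fixture(scope="session")
def small_cohort_frames() -> FrameSet:
    """3 classes x 3 patients x 30 s at 100 Hz -> 99 frames of 500 samples."""
    recs = generate_cohort(default_profiles(3), patients_per_class=3,
                           session_seconds=30.0, fs=100.0, seed=0)
    return frame_recordings(recs)


@pytest.fixture(scope="session")
def two_class_cohort_frames() -> FrameSet:
    """2 classes x 3 patients x 30 s at 100 Hz, for fast harness tests."""
    recs = generate_cohort(default_profiles(2), patients_per_class=3,
                           session_seconds=30.0, fs=100.0, seed=1)
    return frame_recordings(recs)
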