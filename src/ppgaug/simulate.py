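"""Class-conditional synthetic pathological-PPG cohorts.

Every downstream stage (GAN training, kernel metrics, the TSRTR harness)
is exercised on cohorts produced here, so no clinical data is required.
A patient's waveform is a pulse train built from a two-bump beat template
(systolic Gaussian bump plus a delayed, scaled dicrotic bump), amplitude-
modulated by a respiratory sinusoid (emulating respiratory sinus
arrhythmia) and corrupted by white noise.  Disease-severity classes differ
in mean heart rate and respiratory modulation depth, which separates them
in log-power-spectrum space — the representation the classifiers consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PPGRecording

__all__ = ["ClassProfile", "default_profiles", "generate_cohort"]


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters of one severity class.

    hr_mean / hr_sd : beats per minute; hr_sd is the between-patient spread.
    systolic_width : s, standard deviation of the systolic Gaussian bump.
    dicrotic_amp : dicrotic bump amplitude as a fraction of the systolic one.
    dicrotic_delay : s, systolic-to-dicrotic peak delay.
    resp_rate : Hz, respiratory modulation frequency.
    resp_depth : amplitude-modulation fraction in [0, 1).
    noise_sd : additive white-noise standard deviation (amplitude units).
    """

    hr_mean: float
    hr_sd: float = 5.0
    systolic_width: float = 0.10
    dicrotic_amp: float = 0.35
    dicrotic_delay: float = 0.25
    resp_rate: float = 0.25
    resp_depth: float = 0.2
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not self.hr_mean > 0:
            raise ValueError("hr_mean must be positive")
        if not 0 <= self.resp_depth < 1:
            raise ValueError("resp_depth must lie in [0, 1)")
        if not self.dicrotic_delay < 60.0 / self.hr_mean:
            raise ValueError("dicrotic_delay must be shorter than one beat period")


def default_profiles(n_classes: int = 3) -> list[ClassProfile]:
    """Profiles with strictly increasing mean heart rate across classes
    (70, 100, 130 bpm for three classes) and distinct respiratory depth,
    so the classes are separable in the 50-bin feature space."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    profiles = []
    for i in range(n_classes):
        hr = 70.0 + 30.0 * i
        profiles.append(
            ClassProfile(
                hr_mean=hr,
                hr_sd=5.0,
                resp_rate=0.25 + 0.05 * i,
                resp_depth=min(0.1 + 0.1 * i, 0.9),
                dicrotic_delay=min(0.25, 0.5 * 60.0 / hr),
            )
        )
    return profiles


def _beat_train(
    t: np.ndarray, period: float, profile: ClassProfile, rng: np.random.Generator
) -> np.ndarray:
    """Sum of two-bump beat templates at jittered onsets covering t."""
    duration = t[-1]
    n_beats = int(np.ceil(duration / period)) + 2
    onsets = np.arange(-1, n_beats) * period
    # 2 % between-beat jitter avoids a pathological line spectrum
    onsets = onsets + rng.normal(0.0, 0.02 * period, size=onsets.size)
    w = profile.systolic_width
    signal = np.zeros_like(t)
    for onset in onsets:
        # Gaussian support is effectively +-4 w; skip off-window beats
        lo = onset - 4 * w
        hi = onset + profile.dicrotic_delay + 4 * w
        sel = (t >= lo) & (t <= hi)
        if not sel.any():
            continue
        ts = t[sel]
        signal[sel] += np.exp(-0.5 * ((ts - onset) / w) ** 2)
        signal[sel] += profile.dicrotic_amp * np.exp(
            -0.5 * ((ts - onset - profile.dicrotic_delay) / w) ** 2
        )
    return signal


def generate_cohort(
    profiles: list[ClassProfile],
    patients_per_class: int = 5,
    session_seconds: float = 60.0,
    fs: float = 100.0,
    seed: int = 0,
) -> list[PPGRecording]:
    """Simulate one session per patient for every class.

    Each patient draws a personal heart rate from
    ``N(hr_mean, hr_sd^2)`` (clipped to stay positive), receives a jittered
    beat train, respiratory amplitude modulation
    ``1 + resp_depth * sin(2 pi resp_rate t)`` and white noise.  Fully
    reproducible from ``seed``.
    """
    if session_seconds < 10:
        raise ValueError("session_seconds must be at least 10")
    hr_max = max(p.hr_mean for p in profiles)
    if fs < 2 * (hr_max / 60.0 * 5):
        raise ValueError("fs too low to capture the first pulse harmonics")
    rng = np.random.default_rng(seed)
    n_samples = int(round(session_seconds * fs))
    t = np.arange(n_samples) / fs
    recordings: list[PPGRecording] = []
    for cls, profile in enumerate(profiles, start=1):
        for p in range(patients_per_class):
            hr = rng.normal(profile.hr_mean, profile.hr_sd)
            hr = float(np.clip(hr, 0.5 * profile.hr_mean, 1.5 * profile.hr_mean))
            pulse = _beat_train(t, 60.0 / hr, profile, rng)
            envelope = 1.0 + profile.resp_depth * np.sin(
                2 * np.pi * profile.resp_rate * t
            )
            noise = rng.normal(0.0, profile.noise_sd, size=n_samples)
            recordings.append(
                PPGRecording(
                    patient_id=f"C{cls}P{p:02d}",
                    signal=pulse * envelope + noise,
                    fs=fs,
                    severity_class=cls,
                )
            )
    return recordings
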