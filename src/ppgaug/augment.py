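"""Augmentation policies, policy application, and baseline augmenters.

An augmentation policy is a triple (target class, imbalance degree,
synthetic-to-real ratio).  Applying it to a training FrameSet adds
``S = round(ratio * n_real)`` synthetic frames whose per-class counts are
proportional to ``1 + degree * 1[c == target]`` (largest-remainder
rounding), drawn from any object exposing ``sample(n, cls, rng)`` — a
trained CGAN, or one of the baselines here (SpecAugment masking of real
frames, real held-out frames as a positive-control oracle, or a
label-shuffling wrapper as a negative control).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .data import FrameSet

__all__ = [
    "AugmentationPolicy",
    "policy_grid",
    "allocate_synthetic",
    "apply_policy",
    "specaugment",
    "SpecAugmentAugmenter",
    "OracleAugmenter",
    "ShuffledLabelAugmenter",
]

DEFAULT_DEGREES = (0.0, 0.5, 1.0)
DEFAULT_RATIOS = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class AugmentationPolicy:
    """(target class, imbalance degree, synthetic-to-real ratio)."""

    target_class: int
    imbalance_degree: float
    synth_ratio: float

    def __post_init__(self) -> None:
        if self.synth_ratio < 0:
            raise ValueError("synth_ratio must be non-negative")
        if self.imbalance_degree < 0:
            raise ValueError("imbalance_degree must be non-negative")

    @property
    def id(self) -> str:
        return f"c{self.target_class}_d{self.imbalance_degree:g}_r{self.synth_ratio:g}"


def policy_grid(
    classes=(1, 2, 3),
    degrees=DEFAULT_DEGREES,
    ratios=DEFAULT_RATIOS,
) -> list[AugmentationPolicy]:
    """Cartesian product of policy factors, class-major ordering.

    The default grid enumerates 3 classes x 3 degrees x 6 ratios = 54
    policies.
    """
    if not (len(classes) and len(degrees) and len(ratios)):
        raise ValueError("classes, degrees and ratios must be non-empty")
    return [
        AugmentationPolicy(int(c), float(d), float(r))
        for c, d, r in product(classes, degrees, ratios)
    ]


def allocate_synthetic(
    total: int, classes: np.ndarray, policy: AugmentationPolicy
) -> dict[int, int]:
    """Split ``total`` synthetic frames across classes.

    Quotas are proportional to ``1 + degree * 1[c == target]`` and rounded
    by the largest-remainder method (ties broken toward the lower class
    index), so the counts always sum exactly to ``total``.
    """
    classes = np.asarray(classes, dtype=int)
    weights = 1.0 + policy.imbalance_degree * (classes == policy.target_class)
    quotas = total * weights / weights.sum()
    floors = np.floor(quotas).astype(int)
    remainder = total - floors.sum()
    order = np.lexsort((classes, -(quotas - floors)))  # remainder desc, class asc
    for i in order[:remainder]:
        floors[i] += 1
    return dict(zip(classes.tolist(), floors.tolist()))


def apply_policy(
    train: FrameSet, gen, policy: AugmentationPolicy, seed
) -> FrameSet:
    """Augment a training FrameSet according to a policy.

    Real frames are always conserved; synthetic frames are additive only
    and carry the class label used to condition their generation plus a
    ``synthetic`` provenance flag.  A ratio of 0 returns the input
    unchanged.
    """
    if policy.synth_ratio == 0:
        return train
    if gen is None:
        raise ValueError("synth_ratio > 0 requires a generator / augmenter")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = int(round(policy.synth_ratio * len(train)))
    counts = allocate_synthetic(total, train.classes, policy)
    frames = [train.frames]
    labels = [train.labels]
    pids = [train.patient_ids]
    prov = [
        train.provenance
        if train.provenance is not None
        else np.full(len(train), "real")
    ]
    for cls, n_c in counts.items():
        if n_c == 0:
            continue
        synth = gen.sample(n_c, cls, rng)
        if synth.shape != (n_c, train.frame_length):
            raise ValueError("generator produced frames of the wrong shape")
        frames.append(synth)
        labels.append(np.full(n_c, cls))
        pids.append(np.full(n_c, "synthetic"))
        prov.append(np.full(n_c, "synthetic"))
    return FrameSet(
        np.concatenate(frames),
        np.concatenate(labels),
        np.concatenate(pids),
        train.fs,
        train.frame_seconds,
        provenance=np.concatenate(prov),
    )


# ---------------------------------------------------------------------------
# SpecAugment
# ---------------------------------------------------------------------------


def _stft_transform(fs: float, frame_len: int) -> ShortTimeFFT:
    # ~0.5 s Hann window, 75 % overlap; window length trimmed to a multiple
    # of 4 so the hop is integer and the NOLA inversion is exact
    win_len = int(round(0.5 * fs))
    win_len -= win_len % 4
    if win_len < 4 or win_len > frame_len:
        raise ValueError("frame too short for the STFT window")
    return ShortTimeFFT(hann(win_len, sym=False), hop=win_len // 4, fs=fs)


def specaugment(
    fr: FrameSet,
    n_time_masks: int = 2,
    n_freq_masks: int = 2,
    max_width_frac: float = 0.15,
    seed=0,
) -> FrameSet:
    """Mask random time/frequency bands of each frame's spectrogram.

    Each frame is transformed with a short-time Fourier transform (Hann
    window of ~0.5 s, 75 % overlap), the sampled bands are zeroed in the
    complex spectrogram, and the signal is reconstructed with the inverse
    STFT and truncated/padded to the original length.  Deterministic under
    ``seed``; with zero masks the round trip is exact to numerical
    precision.
    """
    if not 0 < max_width_frac < 1:
        raise ValueError("max_width_frac must lie in (0, 1): a mask may not cover a whole axis")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sft = _stft_transform(fr.fs, fr.frame_length)
    out = np.empty_like(fr.frames)
    L = fr.frame_length
    for i, x in enumerate(fr.frames):
        S = sft.stft(x)
        n_freq, n_time = S.shape
        for _ in range(n_time_masks):
            w = int(rng.integers(1, max(int(max_width_frac * n_time), 1) + 1))
            t0 = int(rng.integers(0, n_time - w + 1))
            S[:, t0 : t0 + w] = 0.0
        for _ in range(n_freq_masks):
            w = int(rng.integers(1, max(int(max_width_frac * n_freq), 1) + 1))
            f0 = int(rng.integers(0, n_freq - w + 1))
            S[f0 : f0 + w, :] = 0.0
        rec = sft.istft(S, k1=L)
        out[i] = rec[:L] if rec.size >= L else np.pad(rec, (0, L - rec.size))
    return FrameSet(
        out, fr.labels.copy(), fr.patient_ids.copy(), fr.fs, fr.frame_seconds,
        None if fr.provenance is None else fr.provenance.copy(),
    )


# ---------------------------------------------------------------------------
# Baseline augmenters (all expose sample(n, cls, rng))
# ---------------------------------------------------------------------------


class SpecAugmentAugmenter:
    """Synthesise frames by SpecAugment-masking real frames of a class."""

    def __init__(
        self,
        frames: FrameSet,
        n_time_masks: int = 2,
        n_freq_masks: int = 2,
        max_width_frac: float = 0.15,
    ) -> None:
        self.frames = frames
        self.n_time_masks = n_time_masks
        self.n_freq_masks = n_freq_masks
        self.max_width_frac = max_width_frac

    def sample(self, n: int, cls: int, rng) -> np.ndarray:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        idx = np.flatnonzero(self.frames.labels == cls)
        if idx.size == 0:
            raise ValueError(f"no real frames of class {cls} to mask")
        chosen = rng.choice(idx, size=n, replace=True)
        masked = specaugment(
            self.frames.subset(chosen),
            self.n_time_masks,
            self.n_freq_masks,
            self.max_width_frac,
            seed=rng,
        )
        return masked.frames


class OracleAugmenter:
    """Replay genuine held-back real frames (positive control)."""

    def __init__(self, held_out: FrameSet) -> None:
        self.held_out = held_out

    def sample(self, n: int, cls: int, rng) -> np.ndarray:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        idx = np.flatnonzero(self.held_out.labels == cls)
        if idx.size == 0:
            raise ValueError(f"no held-out frames of class {cls}")
        return self.held_out.frames[rng.choice(idx, size=n, replace=True)]


class ShuffledLabelAugmenter:
    """Negative control: serve frames from a random class under any label."""

    def __init__(self, base, classes) -> None:
        self.base = base
        self.classes = np.asarray(classes, dtype=int)

    def sample(self, n: int, cls: int, rng) -> np.ndarray:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        random_classes = rng.choice(self.classes, size=n)
        out = np.empty((n, 0))
        pieces = []
        for c in np.unique(random_classes):
            k = int(np.sum(random_classes == c))
            pieces.append(self.base.sample(k, int(c), rng))
        return np.concatenate(pieces) if pieces else out
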