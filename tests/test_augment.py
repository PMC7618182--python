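"""Policies, synthetic-frame allocation, SpecAugment and control augmenters."""

import numpy as np
import pytest

from ppgaug import (
    AugmentationPolicy,
    FrameSet,
    OracleAugmenter,
    ShuffledLabelAugmenter,
    SpecAugmentAugmenter,
    apply_policy,
    policy_grid,
    specaugment,
)
from ppgaug.augment import DEFAULT_DEGREES, DEFAULT_RATIOS, allocate_synthetic


class TestPolicyGrid:
    def test_default_size_is_54(self):
        grid = policy_grid()
        assert len(grid) == 54
        assert len({p.id for p in grid}) == 54

    def test_class_major_order(self):
        grid = policy_grid(classes=(1, 2), degrees=(0.0, 1.0), ratios=(0.5,))
        assert [(p.target_class, p.imbalance_degree) for p in grid] == [
            (1, 0.0), (1, 1.0), (2, 0.0), (2, 1.0),
        ]

    def test_validation(self):
        with pytest.raises(ValueError, match="non-negative"):
            AugmentationPolicy(1, -0.5, 0.5)
        with pytest.raises(ValueError, match="non-negative"):
            AugmentationPolicy(1, 0.5, -0.1)
        with pytest.raises(ValueError, match="non-empty"):
            policy_grid(classes=())


class TestAllocation:
    def test_sums_and_bounds(self):
        rng = np.random.default_rng(0)
        classes = np.array([1, 2, 3])
        for _ in range(50):
            total = int(rng.integers(0, 200))
            policy = AugmentationPolicy(
                int(rng.integers(1, 4)), float(rng.choice(DEFAULT_DEGREES)), 1.0
            )
            counts = allocate_synthetic(total, classes, policy)
            assert sum(counts.values()) == total
            weights = 1.0 + policy.imbalance_degree * (classes == policy.target_class)
            quotas = total * weights / weights.sum()
            for cls, q in zip(classes, quotas):
                assert np.floor(q) <= counts[cls] <= np.ceil(q)

    def test_degree_zero_near_equal(self):
        counts = allocate_synthetic(10, np.array([1, 2, 3]), AugmentationPolicy(2, 0.0, 1.0))
        assert sorted(counts.values()) == [3, 3, 4]

    def test_largest_remainder_tie_to_lower_class(self):
        # weights (1, 2, 1), total 150: quotas 37.5 / 75 / 37.5; the single
        # leftover unit goes to the tied class with the lower index
        counts = allocate_synthetic(150, np.array([1, 2, 3]), AugmentationPolicy(2, 1.0, 1.0))
        assert counts == {1: 38, 2: 75, 3: 37}


class _ConstantGen:
    def __init__(self, frame_len):
        self.frame_len = frame_len

    def sample(self, n, cls, rng):
        return np.full((n, self.frame_len), float(cls))


class TestApplyPolicy:
    def test_ratio_zero_is_identity(self, small_cohort_frames):
        policy = AugmentationPolicy(1, 1.0, 0.0)
        assert apply_policy(small_cohort_frames, None, policy, 0) is small_cohort_frames

    def test_counts_and_provenance(self, small_cohort_frames):
        fr = small_cohort_frames
        gen = _ConstantGen(fr.frame_length)
        policy = AugmentationPolicy(2, 1.0, 0.5)
        out = apply_policy(fr, gen, policy, seed=0)
        total = int(round(0.5 * len(fr)))
        assert len(out) == len(fr) + total
        assert int(np.sum(out.provenance == "synthetic")) == total
        # real frames are conserved verbatim at the front
        np.testing.assert_array_equal(out.frames[: len(fr)], fr.frames)
        np.testing.assert_array_equal(out.labels[: len(fr)], fr.labels)
        # synthetic frames carry the conditioning label
        synth = out.provenance == "synthetic"
        np.testing.assert_array_equal(
            out.frames[synth][:, 0], out.labels[synth].astype(float)
        )
        counts = allocate_synthetic(total, fr.classes, policy)
        got = {int(c): int(np.sum(out.labels[synth] == c)) for c in fr.classes}
        assert got == counts

    def test_generator_required(self, small_cohort_frames):
        with pytest.raises(ValueError, match="requires a generator"):
            apply_policy(small_cohort_frames, None, AugmentationPolicy(1, 0.0, 0.5), 0)


class TestSpecAugment:
    def test_zero_masks_round_trip(self, sinusoid_frames):
        sub = sinusoid_frames.subset(np.arange(5))
        out = specaugment(sub, n_time_masks=0, n_freq_masks=0, seed=0)
        np.testing.assert_allclose(out.frames, sub.frames, atol=1e-6)

    def test_masking_changes_and_reduces_energy(self, sinusoid_frames):
        sub = sinusoid_frames.subset(np.arange(5))
        out = specaugment(sub, seed=0)
        assert out.frames.shape == sub.frames.shape
        assert not np.allclose(out.frames, sub.frames)
        # zeroing spectrogram coefficients cannot add energy
        assert np.sum(out.frames**2) < np.sum(sub.frames**2) * 1.01

    def test_deterministic_under_seed(self, sinusoid_frames):
        sub = sinusoid_frames.subset(np.arange(3))
        a = specaugment(sub, seed=5)
        b = specaugment(sub, seed=5)
        c = specaugment(sub, seed=6)
        np.testing.assert_array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_mask_width_validated(self, sinusoid_frames):
        with pytest.raises(ValueError, match="max_width_frac"):
            specaugment(sinusoid_frames.subset([0]), max_width_frac=1.0)

    def test_frequency_mask_kills_band(self):
        """Masking every frequency row but DC leaves almost no energy."""
        fs, L = 100.0, 500
        t = np.arange(L) / fs
        fr = FrameSet(np.sin(2 * np.pi * 10 * t)[None, :], [1], ["p"], fs, 5.0)
        out = specaugment(fr, n_time_masks=0, n_freq_masks=200,
                          max_width_frac=0.5, seed=0)
        assert np.sum(out.frames**2) < 0.05 * np.sum(fr.frames**2)


class TestControlAugmenters:
    def test_specaugment_augmenter(self, sinusoid_frames):
        aug = SpecAugmentAugmenter(sinusoid_frames)
        out = aug.sample(7, 2, np.random.default_rng(0))
        assert out.shape == (7, sinusoid_frames.frame_length)
        with pytest.raises(ValueError, match="no real frames"):
            aug.sample(2, 9, np.random.default_rng(0))

    def test_oracle_serves_class_frames(self, sinusoid_frames):
        aug = OracleAugmenter(sinusoid_frames)
        out = aug.sample(6, 1, np.random.default_rng(0))
        pool = sinusoid_frames.frames[sinusoid_frames.labels == 1]
        for row in out:
            assert any(np.array_equal(row, cand) for cand in pool)

    def test_shuffled_mixes_classes(self, sinusoid_frames):
        oracle = OracleAugmenter(sinusoid_frames)
        shuffled = ShuffledLabelAugmenter(oracle, (1, 2))
        out = shuffled.sample(40, 1, np.random.default_rng(0))
        assert out.shape == (40, sinusoid_frames.frame_length)
        # with 40 draws over 2 classes, both class pools should appear:
        # class-2 frames are 3 Hz tones, class-1 are 1 Hz -> spectra differ
        from ppgaug import log_power_spectrum

        fr = FrameSet(out, np.ones(40, dtype=int), ["s"] * 40,
                      sinusoid_frames.fs, sinusoid_frames.frame_seconds)
        peaks = np.argmax(log_power_spectrum(fr).features, axis=1)
        assert len(set(peaks.tolist())) > 1
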