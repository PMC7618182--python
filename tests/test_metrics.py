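"""Kernel metrics: brute-force oracles, analytic anchors, monotonicity."""

import numpy as np
import pytest

from ppgaug import FrameSet, cmmd, eq_kernel, intraclass_similarity, mmd_report
from ppgaug.metrics import kernel_matrix, standardize_frames

RNG = np.random.default_rng(11)


def brute_force_cmmd(synth, real):
    """Independent triple-loop implementation of the unbiased cMMD."""
    m, n = len(synth), len(real)
    xx = sum(
        np.exp(-np.sum((synth[i] - synth[j]) ** 2))
        for i in range(m)
        for j in range(m)
        if i != j
    ) / (m * (m - 1))
    yy = sum(
        np.exp(-np.sum((real[i] - real[j]) ** 2))
        for i in range(n)
        for j in range(n)
        if i != j
    ) / (n * (n - 1))
    xy = sum(
        np.exp(-np.sum((synth[i] - real[j]) ** 2))
        for i in range(m)
        for j in range(n)
    ) / (m * n)
    return xx - 2 * xy + yy


class TestKernel:
    def test_self_kernel_is_one(self):
        x = RNG.standard_normal(9)
        assert eq_kernel(x, x) == 1.0

    def test_symmetric_and_bounded(self):
        x, y = RNG.standard_normal((2, 6))
        k = eq_kernel(x, y)
        assert k == eq_kernel(y, x)
        assert 0 < k <= 1

    def test_matrix_matches_scalar(self):
        X = RNG.standard_normal((4, 5))
        Y = RNG.standard_normal((3, 5))
        K = kernel_matrix(X, Y)
        for i in range(4):
            for j in range(3):
                assert K[i, j] == pytest.approx(eq_kernel(X[i], Y[j]), abs=1e-14)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            eq_kernel(np.zeros(3), np.zeros(4))


class TestCmmd:
    def test_matches_brute_force(self):
        for m, n, d in ((5, 7, 3), (10, 4, 10), (2, 2, 1)):
            synth = RNG.standard_normal((m, d))
            real = RNG.standard_normal((n, d))
            assert cmmd(synth, real) == pytest.approx(
                brute_force_cmmd(synth, real), abs=1e-12
            )

    def test_identical_sets_non_positive(self):
        X = RNG.standard_normal((8, 4))
        assert cmmd(X, X) <= 1e-12

    def test_distant_point_masses_near_two(self):
        a = np.tile([0.0, 0.0], (5, 1))
        b = np.tile([100.0, 0.0], (5, 1))
        assert cmmd(a, b) == pytest.approx(2.0, abs=1e-12)

    def test_monotone_in_shift(self):
        base = RNG.standard_normal((40, 3))
        ref = RNG.standard_normal((40, 3))
        vals = [cmmd(base + s, ref) for s in (0.0, 1.0, 2.0, 4.0)]
        assert vals == sorted(vals)

    def test_needs_two_vectors(self):
        with pytest.raises(ValueError, match="at least 2"):
            cmmd(np.zeros((1, 3)), np.zeros((4, 3)))


class TestStandardize:
    def test_rows_standardised(self):
        X = RNG.standard_normal((6, 500)) * 3 + 5
        Z = standardize_frames(X, kernel_scale=False)
        np.testing.assert_allclose(Z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=1), 1, atol=1e-12)

    def test_kernel_scale_expected_distance(self):
        # two independent standardised rows: E||x - y||^2 / (2D) ~ 1
        X = standardize_frames(RNG.standard_normal((200, 500)))
        Y = standardize_frames(RNG.standard_normal((200, 500)))
        d2 = np.sum((X - Y) ** 2, axis=1)
        assert d2.mean() == pytest.approx(1.0, abs=0.05)

    def test_constant_row_maps_to_zero(self):
        Z = standardize_frames(np.full((1, 10), 7.0))
        np.testing.assert_array_equal(Z, np.zeros((1, 10)))


class TestIntraclassSimilarity:
    def test_brute_force(self):
        X = RNG.standard_normal((6, 4))
        K, score = intraclass_similarity(X)
        n = 6
        want = sum(
            np.exp(-np.sum((X[i] - X[j]) ** 2))
            for i in range(n)
            for j in range(n)
            if i != j
        ) / (n * (n - 1))
        assert score == pytest.approx(want, abs=1e-12)
        assert K.shape == (6, 6)

    def test_mode_collapse_scores_one(self):
        X = np.tile(RNG.standard_normal(5), (4, 1))
        _, score = intraclass_similarity(X)
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_diverse_scores_near_zero(self):
        X = np.diag(np.full(5, 10.0))
        _, score = intraclass_similarity(X)
        assert score < 1e-6

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="at least 2"):
            intraclass_similarity(np.zeros((1, 3)))


class _NoisySampler:
    """Serves real frames of the requested class plus optional noise."""

    def __init__(self, frames: FrameSet, noise_sd: float = 0.0):
        self.frames = frames
        self.noise_sd = noise_sd

    def sample(self, n, cls, rng):
        idx = np.flatnonzero(self.frames.labels == cls)
        chosen = rng.choice(idx, size=n, replace=True)
        out = self.frames.frames[chosen].copy()
        if self.noise_sd:
            out += rng.normal(0.0, self.noise_sd, size=out.shape)
        return out


class TestMmdReport:
    def test_structure_and_perfect_sampler(self, sinusoid_frames):
        report = mmd_report(
            _NoisySampler(sinusoid_frames), sinusoid_frames,
            n_samples=20, n_seeds=3, seed=0,
        )
        assert list(report.table.index) == ["1", "2", "All"]
        assert set(report.table.columns) >= {"mean", "sd", "n", "flagged"}
        # a sampler replaying real frames should look near-perfect
        assert report.table.loc["All", "mean"] < 0.01
        assert not report.table["flagged"].any()
        assert "All" in str(report)

    def test_noise_raises_mmd(self, sinusoid_frames):
        clean = mmd_report(_NoisySampler(sinusoid_frames), sinusoid_frames,
                           n_samples=20, n_seeds=3, seed=0)
        noisy = mmd_report(_NoisySampler(sinusoid_frames, noise_sd=2.0),
                           sinusoid_frames, n_samples=20, n_seeds=3, seed=0)
        assert noisy.table.loc["All", "mean"] > clean.table.loc["All", "mean"]

    def test_short_class_flagged(self, sinusoid_frames):
        small = sinusoid_frames.subset(np.arange(0, 300, 30))  # 10 frames
        with pytest.warns(UserWarning, match="only"):
            report = mmd_report(_NoisySampler(small), small,
                                n_samples=30, n_seeds=2, seed=0)
        assert report.table["flagged"].drop("All").all()
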