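"""Kernel two-sample metrics for GAN evaluation.

Representativeness is quantified with the (conditional) maximum mean
discrepancy under the exponentiated-quadratic kernel

    K(x, x') = exp(-||x - x'||^2),

which is 1 iff the vectors coincide and decays toward 0 with distance.
The conditional MMD restricts both samples to a single class and uses the
unbiased pair-normalised estimator

    cMMD = sum_{i != i'} K(xh_i, xh_i') / [m(m-1)]
         - 2 sum_{i,j} K(xh_i, x_j) / (mn)
         + sum_{j != j'} K(x_j, x_j') / [n(n-1)],

so values are comparable across sample sizes (and may be slightly negative
on identical distributions).  Intraclass diversity is scored as the mean
off-diagonal kernel entry of a sample-vs-itself kernel matrix: 1 means
total mode collapse, values near 0 mean highly diverse samples.

Raw frames are standardised to zero mean / unit variance per frame before
kernel evaluation (configurable), otherwise ||x - x'||^2 saturates the
exponential for 500-sample inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data import FrameSet

__all__ = [
    "eq_kernel",
    "kernel_matrix",
    "standardize_frames",
    "cmmd",
    "intraclass_similarity",
    "mmd_report",
]


def eq_kernel(x: np.ndarray, y: np.ndarray) -> float:
    """Exponentiated-quadratic kernel of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.exp(-np.sum((x - y) ** 2)))


def kernel_matrix(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Pairwise exponentiated-quadratic kernel matrix."""
    X = np.atleast_2d(X)
    Y = X if Y is None else np.atleast_2d(Y)
    return np.exp(-cdist(X, Y, metric="sqeuclidean"))


def standardize_frames(X: np.ndarray, kernel_scale: bool = True) -> np.ndarray:
    """Zero mean / unit variance per row; constant rows map to zeros.

    With ``kernel_scale`` the rows are further divided by ``sqrt(2 D)`` so
    that two *independent* standardised frames sit at an expected squared
    distance of 1: ``||x - y||^2 / (2 D) = 1 - rho`` for correlation
    ``rho``.  Without this the unit kernel bandwidth saturates for long
    frames (distances of order D) and every off-diagonal kernel entry
    collapses to 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    if kernel_scale:
        Z = Z / np.sqrt(2.0 * X.shape[1])
    return Z


def cmmd(synth: np.ndarray, real: np.ndarray) -> float:
    """Unbiased conditional MMD between class-matched sample sets.

    Lower means the synthetic sample is more similar to the real one; the
    unbiased estimator can go slightly negative and is reported as-is.
    """
    synth = np.atleast_2d(synth)
    real = np.atleast_2d(real)
    m, n = synth.shape[0], real.shape[0]
    if m < 2 or n < 2:
        raise ValueError("need at least 2 vectors in each sample")
    Kxx = kernel_matrix(synth)
    Kyy = kernel_matrix(real)
    Kxy = kernel_matrix(synth, real)
    term_xx = (Kxx.sum() - np.trace(Kxx)) / (m * (m - 1))
    term_yy = (Kyy.sum() - np.trace(Kyy)) / (n * (n - 1))
    term_xy = 2.0 * Kxy.mean()
    return float(term_xx - term_xy + term_yy)


def intraclass_similarity(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Kernel matrix of a sample against itself and its mean off-diagonal.

    A score of 1 flags extreme mode collapse (identical samples); scores
    near 0 indicate diverse samples.  The returned matrix is the full
    symmetric kernel matrix; plotting utilities show its lower triangle.
    """
    samples = np.atleast_2d(samples)
    n = samples.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    K = kernel_matrix(samples)
    off = (K.sum() - np.trace(K)) / (n * (n - 1))
    return K, float(off)


@dataclass
class MMDReport:
    """Per-class and pooled (c)MMD, mean +- sd over sampling seeds."""

    table: pd.DataFrame  # index: class labels + "All"; columns: mean, sd, n, flagged
    n_samples: int
    n_seeds: int

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4f}")


def mmd_report(
    results,
    real: FrameSet,
    n_samples: int = 30,
    n_seeds: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> MMDReport:
    """cMMD per class and pooled MMD between generated and real frames.

    For each of ``n_seeds`` seeds, ``n_samples`` synthetic and ``n_samples``
    real frames are drawn per class; cMMD is computed per class and the
    pooled MMD on the class-merged pools.  ``results`` is anything with a
    ``sample(n, cls, rng)`` method (e.g. :class:`~ppgaug.cgan.CGANResults`).
    """
    rng = np.random.default_rng(seed)
    classes = real.classes
    per_class: dict[int, list[float]] = {int(c): [] for c in classes}
    pooled: list[float] = []
    flagged: dict[int, bool] = {int(c): False for c in classes}
    counts: dict[int, int] = {}

    for _ in range(n_seeds):
        synth_pool, real_pool = [], []
        for cls in classes:
            idx = np.flatnonzero(real.labels == cls)
            n_real = min(n_samples, idx.size)
            if n_real < n_samples and not flagged[int(cls)]:
                warnings.warn(
                    f"class {cls} has only {idx.size} real frames; "
                    f"computing on {n_real}",
                    stacklevel=2,
                )
                flagged[int(cls)] = True
            counts[int(cls)] = n_real
            real_sample = real.frames[rng.choice(idx, size=n_real, replace=False)]
            synth_sample = results.sample(n_samples, int(cls), rng)
            if standardize:
                real_sample = standardize_frames(real_sample)
                synth_sample = standardize_frames(synth_sample)
            per_class[int(cls)].append(cmmd(synth_sample, real_sample))
            synth_pool.append(synth_sample)
            real_pool.append(real_sample)
        pooled.append(cmmd(np.concatenate(synth_pool), np.concatenate(real_pool)))

    rows = []
    for cls in classes:
        vals = np.array(per_class[int(cls)])
        rows.append(
            {
                "class": str(cls),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if n_seeds > 1 else 0.0,
                "n": counts[int(cls)],
                "flagged": flagged[int(cls)],
            }
        )
    pooled_arr = np.array(pooled)
    rows.append(
        {
            "class": "All",
            "mean": pooled_arr.mean(),
            "sd": pooled_arr.std(ddof=1) if n_seeds > 1 else 0.0,
            "n": int(sum(counts.values())),
            "flagged": any(flagged.values()),
        }
    )
    table = pd.DataFrame(rows).set_index("class")
    return MMDReport(table, n_samples, n_seeds)
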