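"""Synthetic generalization curve (SG) and its area (AUSGC).

A point on the curve is the fraction of classification models whose
augmented-scheme metric clears a scaled baseline:

    SG(X, eps) = (1/M) * sum_m 1[ X_TSRTR,m >= (1 - eps) * X_TRTR,m ]

Sweeping eps (eps != 1) yields a metric-agnostic comparison of augmentation
methods: negative eps asks how many models *outperform* the baseline by at
least -eps * 100 percent.  The area under the curve, normalised by the grid
span, is the AUSGC in [0, 1]; on a grid symmetric about 0 a no-effect
augmentation (TSRTR identical to TRTR) lands at 0.5 up to half a grid cell
at the jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SGCurve", "default_epsilon_grid", "sg_point", "sg_curve", "ausgc", "ausgc_summary"]


def default_epsilon_grid() -> np.ndarray:
    """101 evenly spaced points on [-0.5, 0.5]."""
    return np.linspace(-0.5, 0.5, 101)


@dataclass
class SGCurve:
    """Ordered (epsilon, SG) pairs for one policy and metric."""

    epsilons: np.ndarray
    sg: np.ndarray
    policy_id: str = "-"
    metric: str = "auroc"

    def __post_init__(self) -> None:
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        self.sg = np.asarray(self.sg, dtype=float)
        if self.epsilons.ndim != 1 or self.epsilons.shape != self.sg.shape:
            raise ValueError("epsilon grid and sg values must be aligned 1-D arrays")
        if np.any(np.diff(self.epsilons) <= 0):
            raise ValueError("epsilon grid must be strictly increasing")
        if np.any((self.sg < 0) | (self.sg > 1)):
            raise ValueError("sg values must lie in [0, 1]")


def sg_point(x_tsrtr: np.ndarray, x_trtr: np.ndarray, epsilon: float) -> float:
    """Fraction of models meeting ``x_tsrtr >= (1 - epsilon) * x_trtr``."""
    if epsilon == 1:
        raise ValueError("epsilon must differ from 1")
    x_tsrtr = np.asarray(x_tsrtr, dtype=float)
    x_trtr = np.asarray(x_trtr, dtype=float)
    if x_tsrtr.shape != x_trtr.shape or x_tsrtr.ndim != 1:
        raise ValueError("metric vectors must be 1-D and equal length")
    if np.any(x_trtr <= 0):
        raise ValueError("baseline metric values must be positive")
    return float(np.mean(x_tsrtr >= (1.0 - epsilon) * x_trtr))


def sg_curve(
    x_tsrtr: np.ndarray,
    x_trtr: np.ndarray,
    epsilon_grid: np.ndarray | None = None,
    policy_id: str = "-",
    metric: str = "auroc",
) -> SGCurve:
    """Pointwise SG over an epsilon grid (default 101 points on [-0.5, 0.5])."""
    grid = default_epsilon_grid() if epsilon_grid is None else np.asarray(epsilon_grid, float)
    if np.any(grid == 1):
        raise ValueError("epsilon grid may not contain 1")
    sg = np.array([sg_point(x_tsrtr, x_trtr, e) for e in grid])
    return SGCurve(grid, sg, policy_id, metric)


def ausgc(curve: SGCurve) -> float:
    """Trapezoidal area under the SG curve, normalised by the grid span."""
    if curve.epsilons.size < 2:
        raise ValueError("need at least 2 grid points")
    span = curve.epsilons[-1] - curve.epsilons[0]
    return float(np.trapezoid(curve.sg, curve.epsilons) / span)


def ausgc_summary(
    results,
    policies,
    epsilon_grid: np.ndarray | None = None,
    baseline: str | None = None,
) -> pd.DataFrame:
    """AUSGC per augmentation method, mean +- sd across policies.

    ``results`` is a :class:`~ppgaug.harness.HarnessResult` whose TSRTR rows
    cover every policy in ``policies`` for every method; a gap raises an
    error naming the missing (method, policy) pairs.
    """
    baseline = baseline or results.baseline_scheme
    base = results.model_means(baseline)
    methods = sorted(set(results.df.loc[results.df.scheme == "TSRTR", "method"]))
    if not methods:
        raise ValueError("no TSRTR rows in the harness result")
    missing = []
    per_method: dict[str, list[float]] = {m: [] for m in methods}
    for method in methods:
        for policy in policies:
            means = results.model_means("TSRTR", method=method, policy_id=policy.id)
            if means.empty:
                missing.append((method, policy.id))
                continue
            common = means.index.intersection(base.index)
            curve = sg_curve(
                means[common].to_numpy(), base[common].to_numpy(),
                epsilon_grid, policy_id=policy.id,
            )
            per_method[method].append(ausgc(curve))
    if missing:
        raise ValueError(f"missing policy coverage: {missing}")
    rows = []
    for method in methods:
        vals = np.array(per_method[method])
        rows.append(
            {
                "method": method,
                "ausgc_mean": vals.mean(),
                "ausgc_sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                "n_policies": vals.size,
            }
        )
    return pd.DataFrame(rows).set_index("method")
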