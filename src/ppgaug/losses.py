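"""GAN loss functions: diversity sensitivity, generator, discriminator, MADGAN.

The generator objective combines a Jensen-Shannon realism term
``-E[log D(x_hat)]`` (realness score squashed through a sigmoid), an
auxiliary class cross-entropy, and a class-specific diversity-sensitivity
(DS) reward

    L_DS = -E_c E_{z1,z2} [ ||G(z2|c) - G(z1|c)|| / ||z2 - z1|| ]

weighted by ``lambda_div``.  The DS term is never positive: a collapsed
generator that ignores its latent earns the null reward 0, while latent-
sensitive generators are rewarded (more negative loss).

The discriminator combines a Wasserstein term on the raw realness scores,
a zero-centred gradient penalty evaluated at uniform interpolates of real
and synthetic batches, and the auxiliary class cross-entropy on real data.

MADGAN uses one generator per class and a single (C+1)-way softmax head
identifying the source (real or one of the C generators).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import log_softmax, softmax

__all__ = [
    "diversity_sensitivity_loss",
    "ds_loss_and_grads",
    "generator_loss",
    "discriminator_loss",
    "madgan_losses",
]

_LOG_FLOOR = 1e-12


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _pair_ratios(
    g1: np.ndarray, g2: np.ndarray, z1: np.ndarray, z2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair sensitivity ratios; coincident latent pairs are skipped."""
    dz = np.linalg.norm(z2 - z1, axis=1)
    valid = dz > 0
    if not valid.all():
        warnings.warn(
            f"skipping {int((~valid).sum())} coincident latent pair(s): "
            "sensitivity ratio undefined",
            stacklevel=3,
        )
    dg = np.linalg.norm(g2 - g1, axis=1)
    return dg, dz, valid


def diversity_sensitivity_loss(
    g1: np.ndarray,
    g2: np.ndarray,
    z1: np.ndarray,
    z2: np.ndarray,
    pair_classes: np.ndarray | None = None,
) -> float:
    """Class-specific diversity-sensitivity loss (a reward, hence <= 0).

    ``g1``/``g2`` are generator outputs for the latent pairs ``z1``/``z2``;
    both latents of a pair share the class given in ``pair_classes``.  The
    expectation is taken per class first, then averaged over classes; with
    ``pair_classes=None`` all pairs form one class.
    """
    g1, g2 = np.atleast_2d(g1), np.atleast_2d(g2)
    z1, z2 = np.atleast_2d(z1), np.atleast_2d(z2)
    dg, dz, valid = _pair_ratios(g1, g2, z1, z2)
    if pair_classes is None:
        pair_classes = np.zeros(len(dg), dtype=int)
    pair_classes = np.asarray(pair_classes)
    class_means = []
    for cls in np.unique(pair_classes):
        sel = (pair_classes == cls) & valid
        if sel.any():
            class_means.append(np.mean(dg[sel] / dz[sel]))
    if not class_means:
        return 0.0
    return -float(np.mean(class_means))


def ds_loss_and_grads(
    g1: np.ndarray,
    g2: np.ndarray,
    z1: np.ndarray,
    z2: np.ndarray,
    pair_classes: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """DS loss with its gradients wrt the generated pair outputs."""
    g1, g2 = np.atleast_2d(g1), np.atleast_2d(g2)
    z1, z2 = np.atleast_2d(z1), np.atleast_2d(z2)
    dg, dz, valid = _pair_ratios(g1, g2, z1, z2)
    if pair_classes is None:
        pair_classes = np.zeros(len(dg), dtype=int)
    pair_classes = np.asarray(pair_classes)
    grad_g2 = np.zeros_like(g2)
    loss_terms = []
    uniq = [c for c in np.unique(pair_classes) if ((pair_classes == c) & valid).any()]
    for cls in uniq:
        sel = (pair_classes == cls) & valid
        loss_terms.append(np.mean(dg[sel] / dz[sel]))
        # d(-mean ratio)/dg2 = -(g2-g1) / (||dg|| ||dz|| * n_sel * n_classes)
        idx = np.flatnonzero(sel)
        safe_dg = np.where(dg[idx] > 0, dg[idx], 1.0)
        coef = -1.0 / (safe_dg * dz[idx] * sel.sum() * len(uniq))
        grad_g2[idx] = coef[:, None] * (g2[idx] - g1[idx])
    if not loss_terms:
        return 0.0, np.zeros_like(g1), grad_g2
    return -float(np.mean(loss_terms)), -grad_g2, grad_g2


def generator_loss(
    d_scores_fake: np.ndarray,
    class_logits_fake: np.ndarray,
    labels: np.ndarray,
    ds_value: float,
    lambda_div: float = 1e-6,
) -> float:
    """L_G = -mean log sigmoid(d) - mean log softmax(logits)[label] + lambda * L_DS."""
    d_scores_fake = np.asarray(d_scores_fake, dtype=float)
    labels = np.asarray(labels, dtype=int)
    js = -np.mean(np.log(np.maximum(_sigmoid(d_scores_fake), _LOG_FLOOR)))
    logp = log_softmax(np.atleast_2d(class_logits_fake), axis=1)
    aux = -np.mean(logp[np.arange(labels.size), labels - 1])
    return float(js + aux + lambda_div * ds_value)


def discriminator_loss(
    d_scores_real: np.ndarray,
    d_scores_fake: np.ndarray,
    interp_grad_norms: np.ndarray,
    class_logits_real: np.ndarray,
    labels: np.ndarray,
    gp_weight: float = 10.0,
) -> float:
    """Wasserstein + zero-centred gradient penalty + auxiliary class CE.

    L_D = mean(d_fake) - mean(d_real) + gp_weight * mean(||grad||^2)
          - mean(log softmax(logits_real)[label])
    """
    labels = np.asarray(labels, dtype=int)
    wass = float(np.mean(d_scores_fake) - np.mean(d_scores_real))
    gp = float(gp_weight * np.mean(np.asarray(interp_grad_norms, dtype=float) ** 2))
    logp = log_softmax(np.atleast_2d(class_logits_real), axis=1)
    aux = -float(np.mean(logp[np.arange(labels.size), labels - 1]))
    return wass + gp + aux


def madgan_losses(
    d_logits_over_sources: np.ndarray,
    source_labels: np.ndarray,
    per_generator_real_probs: list[np.ndarray],
) -> tuple[float, float]:
    """MADGAN generator and discriminator losses.

    ``d_logits_over_sources``: (n, C+1) logits over sources, column 0 = real,
    columns 1..C = generators.  ``source_labels``: true sources in 0..C.
    ``per_generator_real_probs``: for each generator, the discriminator's
    probability that its samples are real.

    Returns (generator loss = sum of per-generator JS terms,
    discriminator loss = (C+1)-way cross-entropy of source identification).
    """
    logits = np.atleast_2d(d_logits_over_sources)
    source_labels = np.asarray(source_labels, dtype=int)
    n_sources = logits.shape[1]
    if source_labels.size and (source_labels.min() < 0 or source_labels.max() >= n_sources):
        raise ValueError(f"source labels must lie in 0..{n_sources - 1}")
    logp = log_softmax(logits, axis=1)
    d_loss = -float(np.mean(logp[np.arange(source_labels.size), source_labels]))
    g_loss = sum(
        -float(np.mean(np.log(np.maximum(np.asarray(p, dtype=float), _LOG_FLOOR))))
        for p in per_generator_real_probs
    )
    return float(g_loss), d_loss


def softmax_xent_grad(logits: np.ndarray, labels0: np.ndarray) -> np.ndarray:
    """Gradient of mean cross-entropy wrt logits; ``labels0`` are 0-based."""
    logits = np.atleast_2d(logits)
    probs = softmax(logits, axis=1)
    probs[np.arange(labels0.size), labels0] -= 1.0
    return probs / labels0.size
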