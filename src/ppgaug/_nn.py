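"""Minimal NumPy neural-network primitives for the GAN stack.

The generator and discriminator are small fully-connected tanh networks
plus one length-preserving 1-D convolution, so forward passes, reverse-mode
gradients, the input-gradient needed by the gradient penalty, and its
double backprop are written out explicitly here and verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d, correlate1d

__all__ = ["glorot_uniform", "Adam", "conv1d_same", "conv1d_same_vjp"]


def glorot_uniform(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def conv1d_same(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Length-preserving cross-correlation along the last axis, zero-padded.

    ``kernel`` must have odd length so the output is centred.
    """
    if kernel.size % 2 != 1:
        raise ValueError("conv kernel length must be odd")
    return correlate1d(x, kernel, axis=-1, mode="constant", cval=0.0)


def conv1d_same_vjp(
    x: np.ndarray, kernel: np.ndarray, grad_out: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vector-Jacobian products of :func:`conv1d_same`.

    Returns (grad wrt x, grad wrt kernel).  For an odd, zero-padded kernel
    the adjoint of cross-correlation is convolution with the same kernel.
    """
    grad_x = convolve1d(grad_out, kernel, axis=-1, mode="constant", cval=0.0)
    half = kernel.size // 2
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(half, half)])
    L = x.shape[-1]
    grad_k = np.array(
        [np.sum(grad_out * xp[..., j : j + L]) for j in range(kernel.size)]
    )
    return grad_x, grad_k


class Adam:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            self.params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
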