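"""Generator / discriminator architectures, latent samplers and packing.

Both networks are fully connected with tanh activations.  The generator
maps a 50-dimensional latent (concatenated with a one-hot class code)
through widths 100-200-400-500 and finishes with a length-preserving 1-D
convolution that acts as a low-pass filter on the synthetic pulse.  The
discriminator consumes ``p`` packed frames (concatenated along time, which
exposes within-batch mode collapse), runs widths 400-200-100-50 and splits
into two heads: a scalar realness score and class logits.

Latents come either from a standard Gaussian or, for the DeLiGAN variant,
from a learned Gaussian mixture with one component per class
(means trainable, isotropic sigma initialised at 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import conv1d_same, conv1d_same_vjp, glorot_uniform

__all__ = [
    "NetworkSpec",
    "LatentBatch",
    "GMMLatentState",
    "Generator",
    "Discriminator",
    "sample_latent_standard",
    "sample_latent_gmm",
    "generator_forward",
    "discriminator_forward",
    "pack_frames",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters shared by all GAN variants."""

    latent_dim: int = 50
    n_classes: int = 3
    frame_len: int = 500
    gen_widths: tuple[int, ...] = (100, 200, 400)
    disc_widths: tuple[int, ...] = (400, 200, 100, 50)
    packing: int = 3
    conv_kernel: int = 15  # odd; ~0.15 s at 100 Hz
    class_head_dim: int | None = None  # default n_classes; C+1 for MADGAN

    @property
    def head_dim(self) -> int:
        return self.n_classes if self.class_head_dim is None else self.class_head_dim

    @property
    def gen_layer_dims(self) -> tuple[int, ...]:
        return (self.latent_dim + self.n_classes, *self.gen_widths, self.frame_len)

    @property
    def disc_layer_dims(self) -> tuple[int, ...]:
        return (self.frame_len * self.packing, *self.disc_widths)


@dataclass
class LatentBatch:
    """A batch of latent draws with their class conditioning."""

    noise: np.ndarray  # (n, latent_dim)
    class_onehot: np.ndarray  # (n, C), rows sum to 1
    component_ids: np.ndarray | None = None  # (n,) 1..C, DeLiGAN only

    @property
    def generator_input(self) -> np.ndarray:
        return np.concatenate([self.noise, self.class_onehot], axis=1)


@dataclass
class GMMLatentState:
    """Learnable Gaussian-mixture latent prior, one component per class."""

    means: np.ndarray  # (C, latent_dim)
    sigma: float = 0.3

    @classmethod
    def init(cls, spec: NetworkSpec, rng: np.random.Generator, sigma: float = 0.3):
        # "initialized randomly": uniform on [-1, 1] per coordinate
        return cls(rng.uniform(-1.0, 1.0, size=(spec.n_classes, spec.latent_dim)), sigma)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 1 or labels.max() > n_classes):
        raise ValueError(f"labels must lie in 1..{n_classes}")
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels - 1] = 1.0
    return out


def sample_latent_standard(
    n: int, labels: np.ndarray, spec: NetworkSpec, seed
) -> LatentBatch:
    """Standard-Gaussian latent batch: noise ~ N(0, I), one-hot class rows."""
    rng = _as_rng(seed)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (n,):
        raise ValueError("labels must have length n")
    return LatentBatch(rng.standard_normal((n, spec.latent_dim)), _onehot(labels, spec.n_classes))


def sample_latent_gmm(
    n: int, labels: np.ndarray, state: GMMLatentState, seed, n_classes: int | None = None
) -> LatentBatch:
    """GMM latent batch: row i ~ N(means[label_i], sigma^2 I).

    The component is chosen by the class label; the means are the trainable
    parameters updated by the DeLiGAN training loop.
    """
    rng = _as_rng(seed)
    labels = np.asarray(labels, dtype=int)
    C = state.means.shape[0]
    if n_classes is not None and n_classes != C:
        raise ValueError(f"GMM has {C} components but data has {n_classes} classes")
    if labels.shape != (n,):
        raise ValueError("labels must have length n")
    onehot = _onehot(labels, C)
    eps = rng.standard_normal((n, state.means.shape[1]))
    noise = state.means[labels - 1] + state.sigma * eps
    return LatentBatch(noise, onehot, component_ids=labels.copy())


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


class Generator:
    """Fully-connected tanh generator with a final low-pass convolution.

    The convolution kernel is initialised as a boxcar average (a genuine
    low-pass filter) and remains trainable.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        dims = spec.gen_layer_dims
        self.n_layers = len(dims) - 1
        self.params: dict[str, np.ndarray] = {}
        for l in range(1, self.n_layers + 1):
            self.params[f"W{l}"] = glorot_uniform(rng, dims[l], dims[l - 1])
            self.params[f"b{l}"] = np.zeros(dims[l])
        self.params["k"] = np.full(spec.conv_kernel, 1.0 / spec.conv_kernel)
        self.params["kb"] = np.zeros(1)
        self._cache: dict | None = None

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def forward(self, gen_input: np.ndarray, return_preconv: bool = False) -> np.ndarray:
        """Map (n, latent_dim + C) inputs to (n, frame_len) frames."""
        if gen_input.shape[1] != self.spec.gen_layer_dims[0]:
            raise ValueError(
                f"generator input width {gen_input.shape[1]} != "
                f"{self.spec.gen_layer_dims[0]}"
            )
        A = [np.asarray(gen_input, dtype=float)]
        for l in range(1, self.n_layers + 1):
            A.append(np.tanh(A[-1] @ self.params[f"W{l}"].T + self.params[f"b{l}"]))
        preconv = A[-1]
        out = conv1d_same(preconv, self.params["k"]) + self.params["kb"]
        self._cache = {"A": A}
        return (out, preconv) if return_preconv else out

    def backward(self, grad_out: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Reverse-mode pass; returns (parameter grads, grad wrt input)."""
        if self._cache is None:
            raise RuntimeError("call forward before backward")
        A = self._cache["A"]
        grads: dict[str, np.ndarray] = {}
        gA, grads["k"] = conv1d_same_vjp(A[-1], self.params["k"], grad_out)
        grads["kb"] = np.array([grad_out.sum()])
        for l in range(self.n_layers, 0, -1):
            gZ = gA * (1.0 - A[l] ** 2)
            grads[f"W{l}"] = gZ.T @ A[l - 1]
            grads[f"b{l}"] = gZ.sum(axis=0)
            gA = gZ @ self.params[f"W{l}"]
        return grads, gA


def generator_forward(gen: Generator, latent: LatentBatch) -> np.ndarray:
    """Functional wrapper: frames of shape (n, frame_len)."""
    return gen.forward(latent.generator_input)


# ---------------------------------------------------------------------------
# Discriminator
# ---------------------------------------------------------------------------


class Discriminator:
    """Shared tanh trunk with a realness head and a class-logit head."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        dims = spec.disc_layer_dims
        self.n_layers = len(dims) - 1
        self.params: dict[str, np.ndarray] = {}
        for l in range(1, self.n_layers + 1):
            self.params[f"W{l}"] = glorot_uniform(rng, dims[l], dims[l - 1])
            self.params[f"b{l}"] = np.zeros(dims[l])
        self.params["v"] = glorot_uniform(rng, 1, dims[-1])[0]
        self.params["c"] = np.zeros(1)
        self.params["Wc"] = glorot_uniform(rng, spec.head_dim, dims[-1])
        self.params["bc"] = np.zeros(spec.head_dim)
        self._cache: dict | None = None

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def _trunk(self, x: np.ndarray) -> list[np.ndarray]:
        if x.shape[1] != self.spec.disc_layer_dims[0]:
            raise ValueError(
                f"discriminator input width {x.shape[1]} != "
                f"{self.spec.disc_layer_dims[0]} (= frame_len * packing)"
            )
        A = [np.asarray(x, dtype=float)]
        for l in range(1, self.n_layers + 1):
            A.append(np.tanh(A[-1] @ self.params[f"W{l}"].T + self.params[f"b{l}"]))
        return A

    def forward(self, packed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Realness scores (k,) and class logits (k, head_dim)."""
        A = self._trunk(packed)
        scores = A[-1] @ self.params["v"] + self.params["c"][0]
        logits = A[-1] @ self.params["Wc"].T + self.params["bc"]
        self._cache = {"A": A}
        return scores, logits

    def backward(
        self, grad_scores: np.ndarray, grad_logits: np.ndarray
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Reverse-mode pass; returns (parameter grads, grad wrt input)."""
        if self._cache is None:
            raise RuntimeError("call forward before backward")
        A = self._cache["A"]
        grads: dict[str, np.ndarray] = {
            "v": A[-1].T @ grad_scores,
            "c": np.array([grad_scores.sum()]),
            "Wc": grad_logits.T @ A[-1],
            "bc": grad_logits.sum(axis=0),
        }
        gA = grad_scores[:, None] * self.params["v"][None, :] + grad_logits @ self.params["Wc"]
        for l in range(self.n_layers, 0, -1):
            gZ = gA * (1.0 - A[l] ** 2)
            grads[f"W{l}"] = gZ.T @ A[l - 1]
            grads[f"b{l}"] = gZ.sum(axis=0)
            gA = gZ @ self.params[f"W{l}"]
        return grads, gA

    def input_score_gradients(self, x: np.ndarray) -> np.ndarray:
        """Per-row gradient of the realness score wrt the input, shape of x."""
        A = self._trunk(x)
        U = np.broadcast_to(self.params["v"], (x.shape[0], A[-1].shape[1])).copy()
        for l in range(self.n_layers, 0, -1):
            R = U * (1.0 - A[l] ** 2)
            U = R @ self.params[f"W{l}"]
        return U

    def gradient_penalty(
        self, x_interp: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Zero-centred gradient penalty and its parameter gradients.

        Returns ``P = mean_i ||grad_x D(x_i)||^2`` over the interpolated
        batch together with ``dP/dtheta`` for the trunk and realness head,
        computed by differentiating through the input-gradient backprop
        (double backprop).  Verified against finite differences in tests.
        """
        n = x_interp.shape[0]
        A = self._trunk(x_interp)
        T = [None] + [1.0 - A[l] ** 2 for l in range(1, self.n_layers + 1)]

        # input-gradient backprop, keeping intermediates
        U = [None] * (self.n_layers + 1)
        R = [None] * (self.n_layers + 1)
        U[self.n_layers] = np.broadcast_to(
            self.params["v"], (n, A[-1].shape[1])
        ).copy()
        for l in range(self.n_layers, 0, -1):
            R[l] = U[l] * T[l]
            U[l - 1] = R[l] @ self.params[f"W{l}"]
        G = U[0]
        P = float((G**2).sum(axis=1).mean())

        grads = {key: np.zeros_like(val) for key, val in self.params.items()}

        # adjoints through the backprop recursion (low layer -> high layer)
        P_adj = 2.0 * G / n  # dP/dU[0]
        S = [None] * (self.n_layers + 1)
        for l in range(1, self.n_layers + 1):
            Q = P_adj @ self.params[f"W{l}"].T  # dP/dR[l]
            grads[f"W{l}"] += R[l].T @ P_adj
            S[l] = Q * U[l]  # dP/dT[l]
            P_adj = Q * T[l]  # dP/dU[l]
        grads["v"] += P_adj.sum(axis=0)

        # adjoints through the forward pass (T[l] depends on A[l])
        gA = -2.0 * A[self.n_layers] * S[self.n_layers]
        for l in range(self.n_layers, 0, -1):
            gZ = gA * T[l]
            grads[f"W{l}"] += gZ.T @ A[l - 1]
            grads[f"b{l}"] += gZ.sum(axis=0)
            gA = gZ @ self.params[f"W{l}"]
            if l > 1:
                gA += -2.0 * A[l - 1] * S[l - 1]
        return P, grads


def discriminator_forward(
    disc: Discriminator, packed: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper returning (realness scores, class logits)."""
    return disc.forward(packed)


# ---------------------------------------------------------------------------
# Packing
# ---------------------------------------------------------------------------


def pack_frames(frames: np.ndarray, p: int) -> np.ndarray:
    """Concatenate consecutive groups of ``p`` frames along time.

    A remainder of ``m mod p`` frames is dropped; ``m >= p`` is required.
    """
    frames = np.atleast_2d(frames)
    m, L = frames.shape
    if p < 1:
        raise ValueError("packing degree must be >= 1")
    if m < p:
        raise ValueError(f"need at least p={p} frames, got {m}")
    k = m // p
    return frames[: k * p].reshape(k, L * p)
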