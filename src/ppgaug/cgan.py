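"""Conditional GAN variants for class-labelled PPG frames.

Three variants share the architecture in :mod:`ppgaug.networks`:

``cgan_ds``
    Vanilla conditional GAN: class one-hot concatenated to the generator
    latent, plus the class-specific diversity-sensitivity (DS) reward.
``deligan_ds``
    As above, but the latent prior is a learnable Gaussian mixture with one
    component per class (means trained jointly, isotropic sigma = 0.3).
``madgan``
    One generator per class; the discriminator identifies the source of a
    sample (real or one of the C generators) through a (C+1)-way head.

Usage follows the model/results convention::

    model = ConditionalGAN(frames, variant="cgan_ds", epochs=200)
    res = model.fit(seed=0)
    synth = res.sample(30, cls=2, seed=1)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import softmax

from ._nn import Adam
from .data import FrameSet, subsample_balance
from .losses import (
    discriminator_loss,
    ds_loss_and_grads,
    generator_loss,
    madgan_losses,
    softmax_xent_grad,
    _sigmoid,
)
from .networks import (
    Discriminator,
    Generator,
    GMMLatentState,
    LatentBatch,
    NetworkSpec,
    pack_frames,
    sample_latent_gmm,
    sample_latent_standard,
)

__all__ = ["TrainConfig", "ConditionalGAN", "CGANResults"]

VARIANTS = ("cgan_ds", "deligan_ds", "madgan")


@dataclass(frozen=True)
class TrainConfig:
    """Loss and optimisation configuration.

    ``lambda_div`` weights the DS reward (default 1e-6); ``gp_weight``
    weights the zero-centred gradient penalty; ``train_frac`` is the
    class-stratified fraction of frames used as the GAN training pool
    (default 20 %), which is then class-balanced.
    """

    variant: str = "cgan_ds"
    lambda_div: float = 1e-6
    gp_weight: float = 10.0
    epochs: int = 200
    batch_size: int = 64
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    packing: int = 3
    latent_dim: int = 50
    conv_kernel: int = 15
    train_frac: float = 0.2
    balance: bool = True
    gmm_sigma: float = 0.3
    wasserstein_g: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.lambda_div < 0 or self.gp_weight < 0:
            raise ValueError("lambda_div and gp_weight must be non-negative")


def _consecutive_pairs(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into disjoint consecutive pairs (odd leftover dropped)."""
    m = idx.size // 2
    return idx[0 : 2 * m : 2], idx[1 : 2 * m : 2]


def _pack_by_class(
    frames: np.ndarray, labels: np.ndarray, p: int
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Pack frames per class; returns (packed, packed_labels, frame index groups)."""
    packed, packed_labels, groups = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        k = idx.size // p
        if k == 0:
            continue
        grp = idx[: k * p].reshape(k, p)
        packed.append(frames[grp.ravel()].reshape(k, -1))
        packed_labels.append(np.full(k, cls))
        groups.extend(grp)
    if not packed:
        raise ValueError(f"no class had at least p={p} frames to pack")
    return np.concatenate(packed), np.concatenate(packed_labels), groups


def _add_grads(total: dict[str, np.ndarray], part: dict[str, np.ndarray], scale=1.0):
    for key, val in part.items():
        total[key] = total.get(key, 0.0) + scale * val
    return total


class ConditionalGAN:
    """Conditional GAN model bound to a :class:`~ppgaug.data.FrameSet`.

    Keyword overrides are forwarded to :class:`TrainConfig`; ``fit`` runs
    the adversarial loop and returns a :class:`CGANResults`.
    """

    def __init__(
        self,
        frames: FrameSet,
        variant: str = "cgan_ds",
        config: TrainConfig | None = None,
        **overrides,
    ) -> None:
        self.frames = frames
        if config is None:
            config = TrainConfig(variant=variant, **overrides)
        elif overrides or variant != config.variant:
            config = replace(config, variant=variant, **overrides)
        self.config = config
        self.classes = frames.classes
        self.n_classes = int(self.classes.size)
        if not np.array_equal(self.classes, np.arange(1, self.n_classes + 1)):
            raise ValueError("class labels must be consecutive integers 1..C")

    # -- training pool ------------------------------------------------------

    def _training_pool(self, rng: np.random.Generator) -> FrameSet:
        cfg = self.config
        fr = self.frames
        keep: list[np.ndarray] = []
        for cls in self.classes:
            idx = np.flatnonzero(fr.labels == cls)
            n_take = max(int(round(cfg.train_frac * idx.size)), cfg.packing)
            n_take = min(n_take, idx.size)
            keep.append(np.sort(rng.choice(idx, size=n_take, replace=False)))
        pool = fr.subset(np.sort(np.concatenate(keep)))
        if cfg.balance:
            pool = subsample_balance(pool, seed=int(rng.integers(2**31)))
        if min(pool.class_counts().values()) < cfg.packing:
            raise ValueError(
                "fewer frames than one packed group per class in the training pool"
            )
        return pool

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int | None = None) -> "CGANResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        rng_pool, rng_init, rng_train = (np.random.default_rng(s) for s in ss.spawn(3))

        pool = self._training_pool(rng_pool)
        spec = NetworkSpec(
            latent_dim=cfg.latent_dim,
            n_classes=self.n_classes,
            frame_len=pool.frame_length,
            packing=cfg.packing,
            conv_kernel=cfg.conv_kernel,
            class_head_dim=self.n_classes + 1 if cfg.variant == "madgan" else None,
        )
        n_gens = self.n_classes if cfg.variant == "madgan" else 1
        gens = [Generator(spec, rng_init) for _ in range(n_gens)]
        disc = Discriminator(spec, rng_init)
        gmm = (
            GMMLatentState.init(spec, rng_init, cfg.gmm_sigma)
            if cfg.variant == "deligan_ds"
            else None
        )

        gen_opts = [Adam(g.params, lr=cfg.lr_g) for g in gens]
        disc_opt = Adam(disc.params, lr=cfg.lr_d)
        gmm_opt = Adam({"means": gmm.means}, lr=cfg.lr_g) if gmm is not None else None

        history: list[dict[str, float]] = []
        n_pool = len(pool)
        for _epoch in range(cfg.epochs):
            order = rng_train.permutation(n_pool)
            d_losses, g_losses, ds_vals = [], [], []
            for start in range(0, n_pool, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                if batch.size < 2 * cfg.packing:
                    continue
                X = pool.frames[batch]
                y = pool.labels[batch]
                if cfg.variant == "madgan":
                    d_l, g_l = self._step_madgan(
                        X, y, gens, disc, gen_opts, disc_opt, spec, cfg, rng_train
                    )
                    ds_vals.append(0.0)
                else:
                    d_l, g_l, ds_v = self._step_cgan(
                        X, y, gens[0], disc, gen_opts[0], disc_opt,
                        gmm, gmm_opt, spec, cfg, rng_train,
                    )
                    ds_vals.append(ds_v)
                d_losses.append(d_l)
                g_losses.append(g_l)
            history.append(
                {
                    "d_loss": float(np.mean(d_losses)) if d_losses else np.nan,
                    "g_loss": float(np.mean(g_losses)) if g_losses else np.nan,
                    "ds": float(np.mean(ds_vals)) if ds_vals else np.nan,
                }
            )

        return CGANResults(
            variant=cfg.variant,
            spec=spec,
            config=cfg,
            generator_params=[dict(g.params) for g in gens],
            discriminator_params=dict(disc.params),
            gmm_state=gmm,
            history=history,
            classes=self.classes.copy(),
            fs=pool.fs,
            frame_seconds=pool.frame_seconds,
        )

    # -- single optimisation steps ------------------------------------------

    def _sample_latent(self, n, labels, gmm, spec, cfg, rng) -> LatentBatch:
        if cfg.variant == "deligan_ds":
            return sample_latent_gmm(n, labels, gmm, rng, self.n_classes)
        return sample_latent_standard(n, labels, spec, rng)

    def _step_cgan(
        self, X, y, gen, disc, gen_opt, disc_opt, gmm, gmm_opt, spec, cfg, rng
    ) -> tuple[float, float, float]:
        n = X.shape[0]
        p = cfg.packing

        # ---- discriminator update
        latent = self._sample_latent(n, y, gmm, spec, cfg, rng)
        Xf = gen.forward(latent.generator_input)
        packed_r, labels_r, _ = _pack_by_class(X, y, p)
        packed_f, labels_f, _ = _pack_by_class(Xf, y, p)
        k = min(packed_r.shape[0], packed_f.shape[0])
        packed_r, labels_r = packed_r[:k], labels_r[:k]
        packed_f = packed_f[:k]

        d_real, logits_real = disc.forward(packed_r)
        grads_real, _ = disc.backward(
            np.full(k, -1.0 / k), softmax_xent_grad(logits_real, labels_r - 1)
        )
        d_fake, _ = disc.forward(packed_f)
        grads_fake, _ = disc.backward(np.full(k, 1.0 / k), np.zeros((k, spec.head_dim)))

        alpha = rng.uniform(size=(k, 1))
        x_interp = alpha * packed_r + (1 - alpha) * packed_f
        gp_val, gp_grads = disc.gradient_penalty(x_interp)

        d_grads = _add_grads(dict(grads_real), grads_fake)
        d_grads = _add_grads(d_grads, gp_grads, scale=cfg.gp_weight)
        disc_opt.step(d_grads)
        d_loss = discriminator_loss(
            d_real, d_fake, np.sqrt(gp_val) * np.ones(1), logits_real, labels_r,
            cfg.gp_weight,
        )

        # ---- generator update
        latent = self._sample_latent(n, y, gmm, spec, cfg, rng)
        Xf = gen.forward(latent.generator_input)
        packed_f, labels_f, groups = _pack_by_class(Xf, y, p)
        kf = packed_f.shape[0]
        d_fake, logits_fake = disc.forward(packed_f)
        if cfg.wasserstein_g:
            gs = np.full(kf, -1.0 / kf)
        else:
            gs = -(1.0 - _sigmoid(d_fake)) / kf
        glog = softmax_xent_grad(logits_fake, labels_f - 1)
        _, gX = disc.backward(gs, glog)

        gF = np.zeros_like(Xf)
        for row, grp in enumerate(groups):
            gF[grp] += gX[row].reshape(p, -1)

        # diversity-sensitivity reward on disjoint within-class pairs
        # (value recorded even at lambda_div = 0)
        ds_val = 0.0
        i1_all, i2_all, cls_all = [], [], []
        for cls in np.unique(y):
            i1, i2 = _consecutive_pairs(np.flatnonzero(y == cls))
            i1_all.append(i1)
            i2_all.append(i2)
            cls_all.append(np.full(i1.size, cls))
        i1 = np.concatenate(i1_all)
        i2 = np.concatenate(i2_all)
        if i1.size:
            ds_val, gg1, gg2 = ds_loss_and_grads(
                Xf[i1], Xf[i2], latent.noise[i1], latent.noise[i2],
                np.concatenate(cls_all),
            )
            if cfg.lambda_div > 0:
                gF[i1] += cfg.lambda_div * gg1
                gF[i2] += cfg.lambda_div * gg2

        g_grads, gZ = gen.backward(gF)
        gen_opt.step(g_grads)

        if gmm is not None:
            means_grad = np.zeros_like(gmm.means)
            np.add.at(means_grad, y - 1, gZ[:, : cfg.latent_dim])
            gmm_opt.step({"means": means_grad})

        g_loss = generator_loss(d_fake, logits_fake, labels_f, ds_val, cfg.lambda_div)
        return float(d_loss), float(g_loss), float(ds_val)

    def _step_madgan(
        self, X, y, gens, disc, gen_opts, disc_opt, spec, cfg, rng
    ) -> tuple[float, float]:
        p = cfg.packing
        C = self.n_classes

        # ---- discriminator: (C+1)-way source identification, source 0 = real
        packed_r, _, _ = _pack_by_class(X, y, p)
        fakes, fake_sources = [], []
        counts = {cls: int(np.sum(y == cls)) for cls in range(1, C + 1)}
        for cls in range(1, C + 1):
            n_c = max(counts.get(cls, 0), p)
            latent = sample_latent_standard(n_c, np.full(n_c, cls), spec, rng)
            Xf = gens[cls - 1].forward(latent.generator_input)
            pk = pack_frames(Xf, p)
            fakes.append(pk)
            fake_sources.append(np.full(pk.shape[0], cls))
        packed = np.concatenate([packed_r] + fakes)
        sources = np.concatenate([np.zeros(packed_r.shape[0], dtype=int)] + fake_sources)

        _, logits = disc.forward(packed)
        d_grads, _ = disc.backward(
            np.zeros(packed.shape[0]), softmax_xent_grad(logits, sources)
        )
        disc_opt.step(d_grads)

        # ---- generators: per-generator JS toward the "real" source
        g_loss_total = 0.0
        real_probs = []
        for cls in range(1, C + 1):
            n_c = max(counts.get(cls, 0), p)
            latent = sample_latent_standard(n_c, np.full(n_c, cls), spec, rng)
            gen = gens[cls - 1]
            Xf = gen.forward(latent.generator_input)
            packed_f, _, groups = _pack_by_class(
                Xf, np.full(Xf.shape[0], cls), p
            )
            kf = packed_f.shape[0]
            _, logits_f = disc.forward(packed_f)
            glog = softmax_xent_grad(logits_f, np.zeros(kf, dtype=int))
            _, gX = disc.backward(np.zeros(kf), glog)
            gF = np.zeros_like(Xf)
            for row, grp in enumerate(groups):
                gF[grp] += gX[row].reshape(p, -1)
            g_grads, _ = gen.backward(gF)
            gen_opts[cls - 1].step(g_grads)
            real_probs.append(softmax(logits_f, axis=1)[:, 0])

        g_loss_total, d_loss = madgan_losses(logits, sources, real_probs)
        return float(d_loss), float(g_loss_total)


@dataclass
class CGANResults:
    """Trained CGAN: parameters, latent state, loss history, sampling."""

    variant: str
    spec: NetworkSpec
    config: TrainConfig
    generator_params: list[dict[str, np.ndarray]]
    discriminator_params: dict[str, np.ndarray]
    gmm_state: GMMLatentState | None
    history: list[dict[str, float]]
    classes: np.ndarray
    fs: float
    frame_seconds: float

    # -- sampling -----------------------------------------------------------

    def _generator(self, index: int) -> Generator:
        gen = Generator(self.spec, np.random.default_rng(0))
        gen.params.update(
            {k: np.asarray(v, dtype=float) for k, v in self.generator_params[index].items()}
        )
        return gen

    def sample_batch(self, labels: np.ndarray, seed) -> np.ndarray:
        """Generate one frame per entry of ``labels`` (1..C), seeded."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        labels = np.asarray(labels, dtype=int)
        out = np.empty((labels.size, self.spec.frame_len))
        if self.variant == "madgan":
            for cls in np.unique(labels):
                idx = np.flatnonzero(labels == cls)
                latent = sample_latent_standard(
                    idx.size, np.full(idx.size, cls), self.spec, rng
                )
                out[idx] = self._generator(cls - 1).forward(latent.generator_input)
            return out
        if self.variant == "deligan_ds":
            latent = sample_latent_gmm(labels.size, labels, self.gmm_state, rng)
        else:
            latent = sample_latent_standard(labels.size, labels, self.spec, rng)
        return self._generator(0).forward(latent.generator_input)

    def sample(self, n: int, cls: int, seed) -> np.ndarray:
        """Generate ``n`` synthetic frames conditioned on class ``cls``."""
        return self.sample_batch(np.full(n, cls, dtype=int), seed)

    def sample_frameset(self, labels: np.ndarray, seed) -> FrameSet:
        frames = self.sample_batch(labels, seed)
        return FrameSet(
            frames,
            labels,
            np.array([f"synthetic_{self.variant}"] * len(labels)),
            self.fs,
            self.frame_seconds,
            provenance=np.array(["synthetic"] * len(labels)),
        )

    # -- reporting ----------------------------------------------------------

    @property
    def n_params(self) -> dict[str, int]:
        gen_n = sum(sum(v.size for v in g.values()) for g in self.generator_params)
        disc_n = sum(v.size for v in self.discriminator_params.values())
        return {"generator": gen_n, "discriminator": disc_n}

    def loss_history(self) -> dict[str, np.ndarray]:
        keys = self.history[0].keys() if self.history else []
        return {k: np.array([h[k] for h in self.history]) for k in keys}

    def summary(self) -> str:
        np_counts = self.n_params
        lines = [
            "Conditional GAN results",
            "=" * 47,
            f"variant:            {self.variant}",
            f"classes:            {self.classes.tolist()}",
            f"frame length:       {self.spec.frame_len} samples "
            f"({self.frame_seconds:g} s @ {self.fs:g} Hz)",
            f"packing degree:     {self.spec.packing}",
            f"latent dim:         {self.spec.latent_dim}",
            f"lambda_div:         {self.config.lambda_div:g}",
            f"epochs:             {len(self.history)}",
            f"generator params:   {np_counts['generator']}",
            f"discriminator params: {np_counts['discriminator']}",
        ]
        if self.history:
            last = self.history[-1]
            lines.append(
                f"final losses:       D={last['d_loss']:.4f}  G={last['g_loss']:.4f}"
                f"  DS={last['ds']:.4f}"
            )
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: .npz parameter container with a JSON descriptor."""
        arrays: dict[str, np.ndarray] = {}
        for i, gp in enumerate(self.generator_params):
            for key, val in gp.items():
                arrays[f"gen{i}_{key}"] = val
        for key, val in self.discriminator_params.items():
            arrays[f"disc_{key}"] = val
        if self.gmm_state is not None:
            arrays["gmm_means"] = self.gmm_state.means
        hist = {k: [h[k] for h in self.history] for k in (self.history[0] if self.history else {})}
        descriptor = {
            "variant": self.variant,
            "spec": asdict(self.spec),
            "config": asdict(self.config),
            "classes": self.classes.tolist(),
            "fs": self.fs,
            "frame_seconds": self.frame_seconds,
            "n_generators": len(self.generator_params),
            "gmm_sigma": None if self.gmm_state is None else self.gmm_state.sigma,
            "history": hist,
        }
        np.savez(path, descriptor=np.array(json.dumps(descriptor)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CGANResults":
        with np.load(path, allow_pickle=False) as z:
            desc = json.loads(str(z["descriptor"]))
            spec_d = desc["spec"]
            spec_d["gen_widths"] = tuple(spec_d["gen_widths"])
            spec_d["disc_widths"] = tuple(spec_d["disc_widths"])
            spec = NetworkSpec(**spec_d)
            config = TrainConfig(**desc["config"])
            gen_params = []
            for i in range(desc["n_generators"]):
                prefix = f"gen{i}_"
                gen_params.append(
                    {k[len(prefix):]: z[k] for k in z.files if k.startswith(prefix)}
                )
            disc_params = {
                k[len("disc_"):]: z[k] for k in z.files if k.startswith("disc_")
            }
            gmm = None
            if desc["gmm_sigma"] is not None:
                gmm = GMMLatentState(z["gmm_means"], desc["gmm_sigma"])
            hist_d = desc["history"]
            n_epochs = len(next(iter(hist_d.values()))) if hist_d else 0
            history = [
                {k: hist_d[k][i] for k in hist_d} for i in range(n_epochs)
            ]
            return cls(
                variant=desc["variant"],
                spec=spec,
                config=config,
                generator_params=gen_params,
                discriminator_params=disc_params,
                gmm_state=gmm,
                history=history,
                classes=np.array(desc["classes"]),
                fs=desc["fs"],
                frame_seconds=desc["frame_seconds"],
            )
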