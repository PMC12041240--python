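"""Alternating GAN optimization.

Three optimization strategies per batch: (1) the discriminator is stepped
toward labeling real volumes 1 and generated volumes 0 while the generator is
frozen; (2) the generator is stepped on the BerHu + MS-SSIM content terms and
(3) on the non-saturating adversarial BCE, both folded into one composite
objective, while the discriminator is frozen.  AdamW with the stated learning
rates and a ×0.95 decay every 5 epochs; inputs are expected normalized to
(−1, 1).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .losses import (LossConfig, adversarial_losses, berhu, combine_losses,
                     msssim_loss, normalize_unit, denormalize_unit)
from .model import (DiscriminatorSpec, GeneratorSpec, ModelWeights,
                    build_discriminator, build_generator, generator_forward)
from .nn import AdamW, Tensor
from .optics import LightField, ViewStack, Volume, decompose_views


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults are the full-scale reference schedule)."""

    lr_generator: float = 1e-6
    lr_discriminator: float = 1e-7
    adam_betas: tuple = (0.9, 0.999)
    weight_decay: float = 1e-2
    lr_decay_factor: float = 0.95
    lr_decay_every: int = 5          # epochs
    batch_size: int = 2
    epochs: int = 10
    seed: int = 0
    checkpoint_every: int = 5        # epochs between divergence snapshots
    d_steps_per_g: int = 1
    max_steps: int | None = None     # optional hard cap on alternating steps

    def __post_init__(self):
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValueError("learning rates must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def lr_at_epoch(self, epoch: int, base: float) -> float:
        return base * self.lr_decay_factor ** (epoch // self.lr_decay_every)


@dataclass
class TrainHistory:
    """Per-step loss terms and learning rates (serializable)."""

    steps: list = field(default_factory=list)
    seed: int = 0
    diverged: bool = False

    def record(self, **kw):
        self.steps.append(kw)

    def series(self, key: str) -> np.ndarray:
        return np.array([s[key] for s in self.steps if key in s])

    def to_dict(self) -> dict:
        return {"seed": self.seed, "diverged": self.diverged,
                "steps": self.steps}


def _check_pairs(pairs, gspec: GeneratorSpec):
    vshape = (gspec.n_views, *gspec.view_size)
    oshape = gspec.output_shape
    for k, (views, vol) in enumerate(pairs):
        if views.data.shape != vshape:
            raise ValueError(
                f"pair {k}: view stack shape {views.data.shape} != {vshape}")
        if vol.data.shape != oshape:
            raise ValueError(
                f"pair {k}: volume shape {vol.data.shape} != {oshape}")


def _snapshot(module):
    return {k: p.data.copy() for k, p in module.parameters().items()}, \
           {k: b.copy() for k, b in module.buffers().items()}


def _restore(module, snap):
    params, bufs = snap
    for k, p in module.parameters().items():
        p.data = params[k].copy()
    module.load_buffers(bufs)


def train(pairs, gspec: GeneratorSpec, dspec: DiscriminatorSpec,
          loss_cfg: LossConfig, train_cfg: TrainConfig):
    """Alternating discriminator/generator optimization.

    ``pairs`` is a list of (ViewStack, Volume) already normalized to (−1, 1).
    Returns (generator weights, discriminator weights, history).  A NaN loss
    aborts the run and restores the last epoch snapshot.
    """
    _check_pairs(pairs, gspec)
    gw = build_generator(gspec, train_cfg.seed)
    dw = build_discriminator(dspec, train_cfg.seed + 1)
    g_opt = AdamW(gw.module.parameters(), train_cfg.lr_generator,
                  train_cfg.adam_betas, weight_decay=train_cfg.weight_decay)
    d_opt = AdamW(dw.module.parameters(), train_cfg.lr_discriminator,
                  train_cfg.adam_betas, weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed + 2)
    history = TrainHistory(seed=train_cfg.seed)
    snap = (_snapshot(gw.module), _snapshot(dw.module))
    step = 0
    n = len(pairs)
    bs = min(train_cfg.batch_size, n)

    for epoch in range(train_cfg.epochs):
        g_opt.lr = train_cfg.lr_at_epoch(epoch, train_cfg.lr_generator)
        d_opt.lr = train_cfg.lr_at_epoch(epoch, train_cfg.lr_discriminator)
        order = rng.permutation(n)
        for b0 in range(0, n - bs + 1, bs):
            idx = order[b0:b0 + bs]
            views = np.stack([pairs[i][0].data for i in idx])
            real = np.stack([pairs[i][1].data for i in idx])

            # (1) discriminator step, generator frozen (output detached)
            gw.module.eval()
            dw.module.train(True)
            for _ in range(train_cfg.d_steps_per_g):
                fake = gw.module(Tensor(views)).detach()
                d_real = dw.module(Tensor(real))
                d_fake = dw.module(fake)
                d_obj, _ = adversarial_losses(d_real, d_fake)
                d_loss = -d_obj  # maximize the objective
                d_opt.zero_grad()
                d_loss.backward()
                d_opt.step()

            # (2)+(3) generator step on the composite loss, D frozen
            gw.module.train(True)
            dw.module.eval()
            pred = gw.module(Tensor(views, requires_grad=False))
            d_fake2 = dw.module(pred)
            b_term = berhu(pred, Tensor(real), loss_cfg.berhu_c,
                           reduction=loss_cfg.berhu_reduction)
            # MS-SSIM on the (0,1)-mapped intensities
            m_term = msssim_loss((pred + 1.0) * 0.5,
                                 Tensor((real + 1.0) * 0.5), loss_cfg)
            _, g_bce = adversarial_losses(Tensor(np.array(0.5)), d_fake2)
            g_loss = combine_losses(b_term, m_term, g_bce, loss_cfg)
            g_opt.zero_grad()
            g_loss.backward()
            # discriminator stays frozen during the generator step
            for p in dw.module.parameters().values():
                p.zero_grad()
            g_opt.step()

            vals = dict(step=step, epoch=epoch,
                        berhu=float(b_term.item()),
                        msssim_loss=float(m_term.item()),
                        g_bce=float(g_bce.item()),
                        g_total=float(g_loss.item()),
                        d_objective=float(d_obj.item()),
                        lr_g=g_opt.lr, lr_d=d_opt.lr)
            if not all(np.isfinite(v) for v in vals.values()):
                history.diverged = True
                _restore(gw.module, snap[0])
                _restore(dw.module, snap[1])
                gw.module.eval()
                dw.module.eval()
                return gw, dw, history
            history.record(**vals)
            step += 1
            if train_cfg.max_steps is not None and step >= train_cfg.max_steps:
                gw.module.eval()
                dw.module.eval()
                return gw, dw, history
        if (epoch + 1) % train_cfg.checkpoint_every == 0:
            snap = (_snapshot(gw.module), _snapshot(dw.module))
    gw.module.eval()
    dw.module.eval()
    return gw, dw, history


def prepare_pair(lf: LightField, vol: Volume) -> tuple[ViewStack, Volume]:
    """Normalize a raw (light field, volume) pair to (−1, 1) and decompose
    the light field into its sub-aperture views."""
    views = decompose_views(lf)
    return (ViewStack(normalize_unit(views.data), views.pixels_per_lenslet),
            Volume(normalize_unit(vol.data), vol.voxel_size))


def predict(weights: ModelWeights, lf: LightField) -> Volume:
    """Reconstruct a volume from a raw light field with a trained generator.

    decompose views → normalize to (−1, 1) → generator (eval mode) →
    map the output back to [0, 1].  Deterministic for fixed weights.
    """
    gspec: GeneratorSpec = weights.spec
    n = int(round(np.sqrt(gspec.n_views)))
    if lf.pixels_per_lenslet != n:
        raise ValueError(
            f"light field N={lf.pixels_per_lenslet} does not match generator "
            f"N={n}")
    views = decompose_views(lf)
    vn = normalize_unit(views.data)
    out = generator_forward(weights, vn)
    return Volume(np.clip(denormalize_unit(out.data), 0.0, None))


def kfold_split(items, k: int, seed: int = 0):
    """Disjoint k-fold round-robin split: k rounds of (train, validation)
    index arrays; validation folds cover all items exactly once."""
    n = len(items)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of items {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    rounds = []
    for i in range(k):
        val = np.sort(folds[i])
        tr = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        rounds.append((tr, val))
    return rounds
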