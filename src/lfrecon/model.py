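"""View-to-volume GAN: generator and discriminator.

The generator maps the N² sub-aperture views (stacked as channels) to a D-slice
volume at N-fold lateral super-resolution.  It is an encoder–decoder of 3×3
convolution + batch-norm + ReLU blocks with skip connections that concatenate
the *even-indexed channels* of encoder stages 1 and 3 onto the matching decoder
stages, followed by an upsampling head that blends a bicubic interpolation path
with a sub-pixel (pixel-shuffle) convolution path — the blend suppresses the
checkerboard harmonic that a pure pixel-shuffle head produces.

The discriminator scores a volume in (0, 1): five convolutional blocks (first
block at the slice-count channel width, later blocks at 20·2^k), global average
pooling, a 20-unit ReLU dense layer, and a sigmoid head.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .nn import (AdamW, BatchNorm2d, Conv2d, ConvBlock, Dense, Module, Tensor,
                 concat, global_avg_pool, pixel_shuffle, resize_bicubic)
from .optics import ViewStack, Volume

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class GeneratorSpec:
    n_views: int = 169
    view_size: tuple = (16, 16)
    out_slices: int = 61
    upsample_factor: int = 13
    base_channels: int = 64
    skip_layers: tuple = (1, 3)
    skip_channel_rule: str = "even_channels"   # or "all"
    upsample_mode: str = "combined"            # combined | pixelshuffle | bicubic

    def __post_init__(self):
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if not set(self.skip_layers) <= {1, 2, 3}:
            raise ValueError("skip_layers must be encoder stage indices (1..3)")
        if self.skip_channel_rule not in ("even_channels", "all"):
            raise ValueError(f"unknown skip_channel_rule {self.skip_channel_rule!r}")
        if self.upsample_mode not in ("combined", "pixelshuffle", "bicubic"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")

    @property
    def output_shape(self):
        return (self.out_slices,
                self.view_size[0] * self.upsample_factor,
                self.view_size[1] * self.upsample_factor)


@dataclass(frozen=True)
class DiscriminatorSpec:
    in_slices: int = 61
    n_blocks: int = 5
    channel_base: int = 20     # later blocks use channel_base * 2**k
    dense_units: int = 20

    def __post_init__(self):
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")


def _even_channels(x: Tensor) -> Tensor:
    return x[:, ::2]


class Generator(Module):
    def __init__(self, spec: GeneratorSpec, seed: int):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        c = spec.base_channels
        self.enc1 = self.add_child("enc1", ConvBlock(spec.n_views, c, rng))
        self.enc2 = self.add_child("enc2", ConvBlock(c, 2 * c, rng))
        self.enc3 = self.add_child("enc3", ConvBlock(2 * c, 4 * c, rng))

        def skip_width(stage_c):
            if self.spec.skip_channel_rule == "even_channels":
                return (stage_c + 1) // 2
            return stage_c

        dec3_in = 4 * c + (skip_width(4 * c) if 3 in spec.skip_layers else 0)
        self.dec3 = self.add_child("dec3", ConvBlock(dec3_in, 2 * c, rng))
        dec2_in = 2 * c + (skip_width(2 * c) if 2 in spec.skip_layers else 0)
        self.dec2 = self.add_child("dec2", ConvBlock(dec2_in, c, rng))
        dec1_in = c + (skip_width(c) if 1 in spec.skip_layers else 0)
        self.dec1 = self.add_child("dec1", ConvBlock(dec1_in, c, rng))

        ch = max(c // 4, 4)
        self.head_channels = ch
        r = spec.upsample_factor
        if spec.upsample_mode in ("combined", "pixelshuffle"):
            self.ps_conv = self.add_child(
                "ps_conv", Conv2d(c, ch * r * r, 3, rng))
        if spec.upsample_mode in ("combined", "bicubic"):
            self.bc_conv = self.add_child("bc_conv", Conv2d(c, ch, 1, rng, pad=0))
        self.out_conv = self.add_child("out_conv", Conv2d(ch, spec.out_slices, 3, rng))

    def _skip(self, enc_out: Tensor) -> Tensor:
        if self.spec.skip_channel_rule == "even_channels":
            return _even_channels(enc_out)
        return enc_out

    def __call__(self, x: Tensor) -> Tensor:
        s = self.spec
        e1 = self.enc1(x)
        e2 = self.enc2(e1)
        e3 = self.enc3(e2)
        d = e3
        if 3 in s.skip_layers:
            d = concat([d, self._skip(e3)], axis=1)
        d = self.dec3(d)
        if 2 in s.skip_layers:
            d = concat([d, self._skip(e2)], axis=1)
        d = self.dec2(d)
        if 1 in s.skip_layers:
            d = concat([d, self._skip(e1)], axis=1)
        d = self.dec1(d)

        r = s.upsample_factor
        oh = s.view_size[0] * r
        ow = s.view_size[1] * r
        if s.upsample_mode == "pixelshuffle":
            up = pixel_shuffle(self.ps_conv(d), r)
        elif s.upsample_mode == "bicubic":
            up = resize_bicubic(self.bc_conv(d), oh, ow)
        else:
            up = (pixel_shuffle(self.ps_conv(d), r)
                  + resize_bicubic(self.bc_conv(d), oh, ow)) * 0.5
        return self.out_conv(up)


class Discriminator(Module):
    def __init__(self, spec: DiscriminatorSpec, seed: int):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        c_prev = spec.in_slices
        widths = [spec.in_slices] + [
            spec.channel_base * 2 ** k for k in range(1, spec.n_blocks)
        ]
        self.block_widths = widths
        for bi, c_out in enumerate(widths):
            self.add_child(f"block{bi}_a", ConvBlock(c_prev, c_out, rng))
            self.add_child(f"block{bi}_b", ConvBlock(c_out, c_out, rng, stride=2))
            c_prev = c_out
        self.fc1 = self.add_child("fc1", Dense(c_prev, spec.dense_units, rng))
        self.fc2 = self.add_child("fc2", Dense(spec.dense_units, 1, rng))

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for bi in range(self.spec.n_blocks):
            h = self._children[f"block{bi}_a"](h)
            h = self._children[f"block{bi}_b"](h)
        h = global_avg_pool(h)
        h = self.fc1(h).relu()
        return self.fc2(h).sigmoid()


@dataclass
class ModelWeights:
    """A built network with its spec and creation seed (checkpointable)."""

    module: Module
    spec: object
    seed: int
    kind: str  # "generator" | "discriminator"

    def parameter_checksum(self) -> float:
        return self.module.checksum()

    def n_parameters(self) -> int:
        return self.module.n_parameters()


def build_generator(spec: GeneratorSpec, seed: int) -> ModelWeights:
    """Seeded generator construction; identical seeds give identical weights."""
    return ModelWeights(Generator(spec, seed), spec, seed, "generator")


def build_discriminator(spec: DiscriminatorSpec, seed: int) -> ModelWeights:
    return ModelWeights(Discriminator(spec, seed), spec, seed, "discriminator")


def _as_batch(views: ViewStack | np.ndarray, spec: GeneratorSpec) -> np.ndarray:
    data = views.data if isinstance(views, ViewStack) else np.asarray(views)
    if data.ndim == 3:
        data = data[None]
    expected = (spec.n_views, *spec.view_size)
    if data.shape[1:] != expected:
        raise ValueError(
            f"view stack shape {data.shape[1:]} does not match generator spec "
            f"{expected}")
    return data


def generator_forward(weights: ModelWeights, views: ViewStack | np.ndarray,
                      train: bool = False) -> Volume:
    """Run the generator in eval mode (deterministic) on one view stack."""
    if weights.kind != "generator":
        raise ValueError("weights are not a generator checkpoint")
    batch = _as_batch(views, weights.spec)
    weights.module.train(train)
    out = weights.module(Tensor(batch))
    weights.module.eval()
    if not np.all(np.isfinite(out.data)):
        raise FloatingPointError("generator produced non-finite output")
    return Volume(out.data[0])


def discriminator_forward(weights: ModelWeights,
                          volume: Volume | np.ndarray) -> np.ndarray:
    """Score volume(s) in (0, 1); a batch of b volumes returns b scores."""
    if weights.kind != "discriminator":
        raise ValueError("weights are not a discriminator checkpoint")
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if data.ndim == 3:
        data = data[None]
    if data.shape[1] != weights.spec.in_slices:
        raise ValueError(
            f"volume has {data.shape[1]} slices, discriminator expects "
            f"{weights.spec.in_slices}")
    weights.module.eval()
    return weights.module(Tensor(data)).data.reshape(-1)


# ----------------------------------------------------------------- HDF5 I/O


def save_weights(weights: ModelWeights, path):
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["version"] = CHECKPOINT_VERSION
        f.attrs["kind"] = weights.kind
        f.attrs["seed"] = weights.seed
        f.attrs["spec"] = json.dumps(dataclasses.asdict(weights.spec))
        gp = f.create_group("params")
        for k, p in weights.module.parameters().items():
            gp.create_dataset(k, data=p.data)
        gb = f.create_group("buffers")
        for k, b in weights.module.buffers().items():
            gb.create_dataset(k, data=b)


def load_weights(path) -> ModelWeights:
    import h5py

    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        seed = int(f.attrs["seed"])
        spec_d = json.loads(f.attrs["spec"])
        for key in ("view_size", "skip_layers", "z_planes"):
            if key in spec_d and isinstance(spec_d[key], list):
                spec_d[key] = tuple(spec_d[key])
        if kind == "generator":
            w = build_generator(GeneratorSpec(**spec_d), seed)
        else:
            w = build_discriminator(DiscriminatorSpec(**spec_d), seed)
        params = w.module.parameters()
        for k in f["params"]:
            _assign(params, f["params"], k)
        w.module.load_buffers({k: f["buffers"][k][()] for k in f["buffers"]})
    w.module.eval()
    return w


def _assign(params, group, key):
    # h5py flattens group hierarchies only one level here: keys are full names
    params[key].data = group[key][()]
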