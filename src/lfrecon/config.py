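"""Run configuration: one YAML file that carries every tunable of the
pipeline, validated with pydantic (unknown keys rejected), with the
full-scale reference hyperparameters as defaults.

A single global seed fans out deterministically to per-stage seeds
(``stage_seed``) so a whole pipeline run is reproducible from one integer.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .losses import LossConfig
from .metrics import FeatureExtractorConfig
from .model import DiscriminatorSpec, GeneratorSpec
from .optics import OpticalConfig
from .phantoms import PhantomSpec
from .piv import FlowParams
from .training import TrainConfig


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsSection(_Section):
    magnification: float = 63.0
    numerical_aperture: float = 1.4
    wavelength: float = 525.0
    medium_index: float = 1.518
    lenslet_pitch: float = 1.3
    pixels_per_lenslet: int = 13
    sensor_pixel: float = 0.1
    z_planes: list[float] = [-3.0, -1.5, 0.0, 1.5, 3.0]
    psf_model: str = "gaussian_defocus"
    kernel_halfwidth: int = 2
    gauss_sigma0: float = 0.3
    gauss_sigma_slope: float = 0.05
    disparity_slope: float | None = None

    def build(self) -> OpticalConfig:
        d = self.model_dump()
        d["z_planes"] = tuple(d["z_planes"])
        return OpticalConfig(**d)


class PhantomSection(_Section):
    shape: list[int] = [5, 64, 64]
    voxel_size: list[float] = [1.0, 0.1, 0.1]
    kind: str = "beads"           # tubulins | beads | neuro | particles
    n_filaments: int = 10
    filament_diameter: float = 1.0
    n_beads: int = 10
    bead_diameter: float = 0.1
    min_separation: float = 1.0
    n_somata: int = 8
    with_background: bool = False
    particles_per_lenslet: float = 0.03
    flow: str = "uniform"

    def build(self, seed: int, pixels_per_lenslet: int = 4) -> PhantomSpec:
        d = self.model_dump()
        d.pop("kind")
        d["shape"] = tuple(d["shape"])
        d["voxel_size"] = tuple(d["voxel_size"])
        return PhantomSpec(seed=seed, pixels_per_lenslet=pixels_per_lenslet, **d)


class GeneratorSection(_Section):
    base_channels: int = 64
    skip_layers: list[int] = [1, 3]
    skip_channel_rule: str = "even_channels"
    upsample_mode: str = "combined"


class DiscriminatorSection(_Section):
    n_blocks: int = 5
    channel_base: int = 20
    dense_units: int = 20


class LossSection(_Section):
    alpha: float = 3.0
    beta: float = 1.0
    gamma: float = 0.5
    berhu_c: float = 0.1
    berhu_reduction: str = "sum"
    msssim_levels: int = 5
    dynamic_range: float = 1.0
    msssim_window: int = 11
    msssim_sigma: float = 1.5

    def build(self) -> LossConfig:
        return LossConfig(**self.model_dump())


class TrainSection(_Section):
    lr_generator: float = 1e-6
    lr_discriminator: float = 1e-7
    adam_betas: list[float] = [0.9, 0.999]
    weight_decay: float = 1e-2
    lr_decay_factor: float = 0.95
    lr_decay_every: int = 5
    batch_size: int = 2
    epochs: int = 10
    checkpoint_every: int = 5
    d_steps_per_g: int = 1
    max_steps: int | None = None

    @field_validator("lr_generator", "lr_discriminator")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("learning rates must be > 0")
        return v

    def build(self, seed: int) -> TrainConfig:
        d = self.model_dump()
        d["adam_betas"] = tuple(d["adam_betas"])
        return TrainConfig(seed=seed, **d)


class ReconSection(_Section):
    n_iterations: int = 30
    stop_tolerance: float = 0.0


class FlowSection(_Section):
    regularization: float = 0.05
    n_iterations: int = 300
    pyramid_levels: int = 2
    n_warps: int = 4

    def build(self) -> FlowParams:
        return FlowParams(**self.model_dump())


class MetricSection(_Section):
    max_i: float = 1.0
    lpips_seed: int = 0
    ssim_mode: str = "global"

    def feature_config(self) -> FeatureExtractorConfig:
        return FeatureExtractorConfig(seed=self.lpips_seed)


class RunConfig(_Section):
    seed: int = 0
    output_dir: str = "lfrecon_out"
    optics: OpticsSection = OpticsSection()
    phantom: PhantomSection = PhantomSection()
    generator: GeneratorSection = GeneratorSection()
    discriminator: DiscriminatorSection = DiscriminatorSection()
    loss: LossSection = LossSection()
    train: TrainSection = TrainSection()
    recon: ReconSection = ReconSection()
    flow: FlowSection = FlowSection()
    metrics: MetricSection = MetricSection()

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig(**data)


def save_config(cfg: RunConfig, path):
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
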