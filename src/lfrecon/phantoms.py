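"""Seeded synthetic phantoms mirroring the sample classes used to evaluate
light-field reconstruction: filamentous tubulin, sub-diffraction beads,
simplified cortical volumes with calcium dynamics, and seeded particle
fields advected by analytic flows for PIV.

Every generator is a pure function of its spec (seed included) and returns
machine-readable ground truth alongside the rendered volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .optics import Volume

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic sample.

    ``shape`` is (D, H, W) voxels; ``voxel_size`` is μm per voxel (z, y, x).
    Class-specific fields are ignored by generators that do not use them.
    """

    shape: tuple = (5, 64, 64)
    voxel_size: tuple = (1.0, 0.1, 0.1)
    seed: int = 0
    # tubulins
    n_filaments: int = 10
    filament_diameter: float = 1.0        # μm (rasterized FWHM)
    n_control_points: int = 5
    # beads
    n_beads: int = 10
    bead_diameter: float = 0.1            # μm (FWHM of the Gaussian spot)
    min_separation: float = 1.0           # μm
    # neuro
    n_somata: int = 8
    soma_radius: float = 7.0              # μm
    with_background: bool = False
    n_vessels: int = 3
    neuropil_level: float = 0.15
    frame_rate: float = 10.0              # Hz
    n_frames: int = 100
    spike_rate: float = 0.2               # Hz, Poisson
    decay_tau: float = 1.0                # s, single-exponential indicator
    trace_noise: float = 0.0
    # particles / PIV
    particles_per_lenslet: float = 0.03   # PPM seeding density
    pixels_per_lenslet: int = 4
    particle_diameter: float = 2.0        # voxels (FWHM)
    flow: str = "uniform"                 # uniform | shear | vortex
    flow_speed: float = 1.0               # voxels/frame (uniform/shear scale)
    vortex_omega: float = 0.05            # rad/frame
    frame_time: float = 0.025             # s

    def __post_init__(self):
        if self.particles_per_lenslet < 0:
            raise ValueError("particle density must be >= 0")
        if min(self.shape) < 1:
            raise ValueError("shape must be positive")


@dataclass
class ParticleSet:
    """Point-like objects with positions in voxel coordinates (z, y, x)."""

    positions: np.ndarray          # (n, 3) float, voxel units
    diameters: np.ndarray          # (n,) voxels
    frame_time: float = 0.0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = np.zeros((0, 3))
        self.diameters = np.asarray(self.diameters, dtype=float).reshape(-1)

    def __len__(self):
        return self.positions.shape[0]


@dataclass
class ActivityTrace:
    """Fluorescence time series of one neuron at ``frame_rate`` Hz."""

    values: np.ndarray
    frame_rate: float
    spike_times: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")


@dataclass
class FlowField:
    """Velocity field (3, D, H, W) in voxels/frame plus frame interval."""

    vectors: np.ndarray
    frame_time: float = 0.0
    units: str = "voxels/frame"

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValueError(f"flow must be (3, D, H, W), got {self.vectors.shape}")


# ------------------------------------------------------------------ tubulins


def make_tubulins(spec: PhantomSpec) -> Volume:
    """Random smooth 3D filaments with Gaussian cross-section.

    Each filament is a cubic spline through ``n_control_points`` uniform
    control points, rasterized as a dense polyline and blurred so the
    cross-section FWHM equals ``filament_diameter``.
    """
    d, h, w = spec.shape
    sig_vox = np.array([
        spec.filament_diameter / _FWHM / spec.voxel_size[0],
        spec.filament_diameter / _FWHM / spec.voxel_size[1],
        spec.filament_diameter / _FWHM / spec.voxel_size[2],
    ])
    extent = np.array(spec.shape) * np.array(spec.voxel_size)
    if spec.filament_diameter > extent.min():
        raise ValueError(
            f"filament diameter {spec.filament_diameter} μm exceeds the "
            f"smallest volume extent {extent.min()} μm"
        )
    rng = np.random.default_rng(spec.seed)
    vol = np.zeros(spec.shape)
    for _ in range(spec.n_filaments):
        ctrl = rng.uniform(0, 1, size=(spec.n_control_points, 3))
        ctrl *= np.array([d - 1, h - 1, w - 1])
        t = np.linspace(0, 1, spec.n_control_points)
        cs = CubicSpline(t, ctrl, axis=0)
        n_samp = 20 * max(h, w)
        pts = cs(np.linspace(0, 1, n_samp))
        idx = np.round(pts).astype(int)
        keep = np.all((idx >= 0) & (idx < np.array(spec.shape)), axis=1)
        idx = idx[keep]
        np.add.at(vol, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    # equalize deposit density, then shape the cross-section
    vol = np.minimum(vol, np.percentile(vol[vol > 0], 50) if np.any(vol > 0) else 1.0)
    vol = gaussian_filter(vol, sigma=sig_vox)
    if vol.max() > 0:
        vol /= vol.max()
    return Volume(data=vol, voxel_size=tuple(spec.voxel_size))


# --------------------------------------------------------------------- beads


def _rasterize_beads(shape, positions, sigmas_vox, amplitudes=None):
    """Render Gaussian spots at sub-voxel positions (analytic, no aliasing)."""
    vol = np.zeros(shape)
    if amplitudes is None:
        amplitudes = np.ones(len(positions))
    for p, s, a in zip(positions, sigmas_vox, amplitudes):
        lo = np.maximum(np.floor(p - 4 * s).astype(int), 0)
        hi = np.minimum(np.ceil(p + 4 * s).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz = np.arange(lo[0], hi[0])[:, None, None]
        yy = np.arange(lo[1], hi[1])[None, :, None]
        xx = np.arange(lo[2], hi[2])[None, None, :]
        g = a * np.exp(
            -((zz - p[0]) ** 2 / (2 * s[0] ** 2)
              + (yy - p[1]) ** 2 / (2 * s[1] ** 2)
              + (xx - p[2]) ** 2 / (2 * s[2] ** 2))
        )
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += g
    return vol


def make_beads(spec: PhantomSpec) -> tuple[Volume, ParticleSet]:
    """Isolated Gaussian beads at random positions with a minimum separation.

    Returned positions (voxel coordinates, sub-voxel precision) are the
    ground truth for localization scoring.
    """
    if spec.n_beads == 0:
        return (Volume(np.zeros(spec.shape), tuple(spec.voxel_size)),
                ParticleSet(np.zeros((0, 3)), np.zeros(0)))
    rng = np.random.default_rng(spec.seed)
    vs = np.array(spec.voxel_size)
    margin = 3.0
    lo = np.full(3, margin)
    hi = np.array(spec.shape) - 1 - margin
    if np.any(hi <= lo):
        lo = np.ones(3)
        hi = np.array(spec.shape) - 2.0
    positions = []
    attempts = 0
    max_attempts = 2000 * spec.n_beads
    while len(positions) < spec.n_beads:
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_beads} beads with min_separation "
                f"{spec.min_separation} μm after {max_attempts} attempts"
            )
        attempts += 1
        cand = rng.uniform(lo, hi)
        if positions:
            dists = np.linalg.norm((np.array(positions) - cand) * vs, axis=1)
            if dists.min() < spec.min_separation:
                continue
        positions.append(cand)
    positions = np.array(positions)
    sigma_um = spec.bead_diameter / _FWHM
    sigmas = np.tile(sigma_um / vs, (spec.n_beads, 1))
    sigmas = np.maximum(sigmas, 0.6)  # keep the spot resolvable on the grid
    vol = _rasterize_beads(spec.shape, positions, sigmas)
    if vol.max() > 0:
        vol /= vol.max()
    return (Volume(vol, tuple(spec.voxel_size)),
            ParticleSet(positions, np.full(spec.n_beads, spec.bead_diameter)))


# --------------------------------------------------------------------- neuro


def make_activity_traces(spec: PhantomSpec, n: int | None = None) -> list[ActivityTrace]:
    """GCaMP-style traces: Poisson spikes convolved with a single-exponential
    kernel of time constant ``decay_tau``, optional additive Gaussian noise."""
    n = spec.n_somata if n is None else n
    rng = np.random.default_rng(spec.seed + 101)
    dt = 1.0 / spec.frame_rate
    t = np.arange(spec.n_frames) * dt
    kernel = np.exp(-t / spec.decay_tau)
    traces = []
    for _ in range(n):
        spikes = rng.random(spec.n_frames) < spec.spike_rate * dt
        f = np.convolve(spikes.astype(float), kernel)[: spec.n_frames]
        f = 0.2 + f  # resting fluorescence
        if spec.trace_noise > 0:
            f = f + rng.normal(0, spec.trace_noise, spec.n_frames)
        traces.append(ActivityTrace(values=f, frame_rate=spec.frame_rate,
                                    spike_times=t[spikes]))
    return traces


def make_neuro_volume(spec: PhantomSpec) -> tuple[Volume, ParticleSet, list[ActivityTrace]]:
    """Simplified cortical volume: soma ellipsoids, optional neuropil haze and
    dark vessel tubes, with per-soma calcium traces.

    The returned volume shows every soma at its resting brightness
    (trace value of frame 0); :func:`render_neuro_frames` produces the
    time-resolved stack.  Soma centers are the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    d, h, w = spec.shape
    vs = np.array(spec.voxel_size)
    r_vox = spec.soma_radius / vs
    # keep soma centers inside the volume; when a soma is larger than an
    # axis extent, center it on that axis
    ext = np.array(spec.shape, dtype=float) - 1
    lo = np.minimum(np.maximum(r_vox, 0.5), ext / 2)
    hi = np.maximum(ext - lo, lo + 1e-9)
    centers = rng.uniform(lo, hi, size=(spec.n_somata, 3)) \
        if spec.n_somata else np.zeros((0, 3))
    traces = make_activity_traces(spec)

    zz, yy, xx = np.meshgrid(np.arange(d), np.arange(h), np.arange(w),
                             indexing="ij")
    soma_masks = []
    for c in centers:
        m = (((zz - c[0]) / r_vox[0]) ** 2 + ((yy - c[1]) / r_vox[1]) ** 2
             + ((xx - c[2]) / r_vox[2]) ** 2) <= 1.0
        soma_masks.append(m)

    background = np.zeros(spec.shape)
    if spec.with_background:
        haze = gaussian_filter(rng.random(spec.shape), sigma=(1, 6, 6))
        haze -= haze.min()
        if haze.max() > 0:
            haze /= haze.max()
        background = spec.neuropil_level * haze
        for _ in range(spec.n_vessels):
            y0 = rng.uniform(0, h)
            ang = rng.uniform(0, np.pi)
            dist = np.abs((yy - y0) * np.cos(ang) - (xx - w / 2) * np.sin(ang))
            background *= np.where(dist < 2.0, 0.2, 1.0)

    vol = background.copy()
    for m, tr in zip(soma_masks, traces):
        vol = np.where(m, tr.values[0], vol)
    volume = Volume(vol, tuple(spec.voxel_size))
    volume._soma_masks = soma_masks  # cached for frame rendering
    return (volume,
            ParticleSet(centers, np.full(len(centers), 2 * spec.soma_radius)),
            traces)


def render_neuro_frames(spec: PhantomSpec) -> tuple[np.ndarray, ParticleSet, list[ActivityTrace]]:
    """Time-resolved 4D stack (T, D, H, W): soma brightness follows each trace."""
    base, centers, traces = make_neuro_volume(spec)
    masks = base._soma_masks
    frames = np.empty((spec.n_frames, *spec.shape))
    static = base.data.copy()
    for m in masks:
        static = np.where(m, 0.0, static)
    for ti in range(spec.n_frames):
        f = static.copy()
        for m, tr in zip(masks, traces):
            f = np.where(m, tr.values[ti], f)
        frames[ti] = f
    return frames, centers, traces


# ----------------------------------------------------------------- particles


def analytic_flow(kind: str, shape, spec: PhantomSpec) -> np.ndarray:
    """Velocity field (3, D, H, W) in voxels/frame on the voxel grid.

    ``uniform``  — constant (0, 0, flow_speed) along x.
    ``shear``    — lid-driven-like: u_x grows linearly with depth z.
    ``vortex``   — solid-body rotation in the x–z plane about the volume
                   center at ``vortex_omega`` rad/frame.
    """
    d, h, w = shape
    zz, yy, xx = np.meshgrid(np.arange(d, dtype=float), np.arange(h, dtype=float),
                             np.arange(w, dtype=float), indexing="ij")
    u = np.zeros((3, d, h, w))
    if kind == "uniform":
        u[2] = spec.flow_speed
    elif kind == "shear":
        u[2] = spec.flow_speed * zz / max(d - 1, 1)
    elif kind == "vortex":
        z0, x0 = (d - 1) / 2.0, (w - 1) / 2.0
        u[0] = spec.vortex_omega * (xx - x0)
        u[2] = -spec.vortex_omega * (zz - z0)
    else:
        raise ValueError(f"unknown flow descriptor {kind!r}")
    return u


def _advect(positions: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.flow == "uniform":
        return positions + np.array([0.0, 0.0, spec.flow_speed])
    if spec.flow == "shear":
        d = spec.shape[0]
        out = positions.copy()
        out[:, 2] += spec.flow_speed * positions[:, 0] / max(d - 1, 1)
        return out
    if spec.flow == "vortex":
        d, _, w = spec.shape
        z0, x0 = (d - 1) / 2.0, (w - 1) / 2.0
        out = positions.copy()
        dz = positions[:, 0] - z0
        dx = positions[:, 2] - x0
        cw, sw = np.cos(spec.vortex_omega), np.sin(spec.vortex_omega)
        out[:, 0] = z0 + cw * dz + sw * dx
        out[:, 2] = x0 - sw * dz + cw * dx
        return out
    raise ValueError(f"unknown flow descriptor {spec.flow!r}")


def make_particle_pair(spec: PhantomSpec) -> tuple[Volume, Volume, ParticleSet,
                                                   ParticleSet, FlowField]:
    """Two consecutive frames of a seeded particle field.

    Frame-1 particle count is Poisson with mean
    ``particles_per_lenslet × lenslet count`` (the PPM seeding convention);
    frame-2 positions are the frame-1 positions advected by the analytic
    flow over one frame.  The flow sampled on the voxel grid is returned
    as ground truth.
    """
    d, h, w = spec.shape
    n = spec.pixels_per_lenslet
    n_lenslets = (h // n) * (w // n)
    rng = np.random.default_rng(spec.seed)
    count = rng.poisson(spec.particles_per_lenslet * n_lenslets)
    margin = 2.0
    p1 = rng.uniform([margin] * 3, np.array(spec.shape) - 1 - margin,
                     size=(count, 3)) if count else np.zeros((0, 3))
    p2 = _advect(p1, spec) if count else p1.copy()
    sigma = max(spec.particle_diameter / _FWHM, 0.6)
    sigmas = np.full((count, 3), sigma)
    v1 = _rasterize_beads(spec.shape, p1, sigmas)
    v2 = _rasterize_beads(spec.shape, p2, sigmas)
    peak = max(v1.max(), v2.max(), 1e-12)
    v1 /= peak
    v2 /= peak
    diam = np.full(count, spec.particle_diameter)
    flow = FlowField(analytic_flow(spec.flow, spec.shape, spec),
                     frame_time=spec.frame_time)
    return (Volume(v1, tuple(spec.voxel_size)), Volume(v2, tuple(spec.voxel_size)),
            ParticleSet(p1, diam, spec.frame_time),
            ParticleSet(p2, diam, spec.frame_time), flow)


def add_camera_noise(lf_data: np.ndarray, seed: int, photons: float = 1000.0,
                     read_sigma: float = 0.01) -> np.ndarray:
    """Optional Poisson + Gaussian read-noise hook for projected light fields."""
    rng = np.random.default_rng(seed)
    scaled = np.maximum(lf_data, 0) * photons
    noisy = rng.poisson(scaled) / photons
    return noisy + rng.normal(0, read_sigma, lf_data.shape)
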