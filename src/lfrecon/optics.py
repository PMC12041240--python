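"""Wave-optics forward model of light-field microscopy.

A microlens array at the native image plane turns one camera frame into an
N x N angular sampling behind every lenslet.  The forward model is linear:
every voxel of a 3D volume, at depth ``z_d`` and sub-lenslet phase ``(i, j)``,
stamps a fixed kernel onto the sensor at its lenslet's position.  The kernel
bank is therefore indexed ``(depth, phase_i, phase_j, row, col)`` and the
model is shift-invariant over integer lenslet pitches only.

Two PSF models are provided:

* ``wave_optics`` — scalar-diffraction model: pupil-limited defocused field at
  the native image plane, lenslet phase mask, Fresnel propagation to the
  sensor, intensity sampling.
* ``gaussian_defocus`` — fast surrogate: the angular component ``(a, b)`` of a
  source at depth ``z`` lands at lenslet disparity ``s*z*(a-c, b-c)`` with a
  Gaussian footprint that widens with ``|z|``.  Same disparity law as the
  refocusing baseline, so depth information is preserved.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve


class ConfigurationError(ValueError):
    """Raised when optical parameters violate their invariants."""


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition geometry of the light-field system (sample-referred units).

    Parameters
    ----------
    magnification : objective magnification (bookkeeping only; all lengths
        here are already divided by it).
    numerical_aperture : NA of the objective; must be < ``medium_index``.
    wavelength : emission wavelength in nm.
    medium_index : refractive index of the immersion medium.
    lenslet_pitch : microlens pitch in μm, sample-referred.
    pixels_per_lenslet : N, angular samples per lenslet axis.
    sensor_pixel : sensor pixel size in μm, sample-referred
        (= lenslet_pitch / N for a matched array).
    z_planes : strictly increasing depths (μm) of the reconstruction planes.
    psf_model : ``"wave_optics"`` or ``"gaussian_defocus"``.
    kernel_halfwidth : kernel support half-width in lenslet pitches.
    """

    magnification: float = 63.0
    numerical_aperture: float = 1.4
    wavelength: float = 525.0
    medium_index: float = 1.518
    lenslet_pitch: float = 1.3
    pixels_per_lenslet: int = 13
    sensor_pixel: float = 0.1
    z_planes: tuple = (-3.0, -1.5, 0.0, 1.5, 3.0)
    psf_model: str = "gaussian_defocus"
    kernel_halfwidth: int = 2
    # gaussian_defocus surrogate knobs (lenslet units / per-μm)
    gauss_sigma0: float = 0.3
    gauss_sigma_slope: float = 0.05
    disparity_slope: float | None = None  # lenslets per μm per pixel offset

    def __post_init__(self):
        if self.numerical_aperture >= self.medium_index:
            raise ConfigurationError(
                f"numerical_aperture ({self.numerical_aperture}) must be < "
                f"medium_index ({self.medium_index})"
            )
        if self.pixels_per_lenslet < 1:
            raise ConfigurationError("pixels_per_lenslet must be >= 1")
        if self.kernel_halfwidth < 0:
            raise ConfigurationError("kernel_halfwidth must be >= 0")
        z = np.asarray(self.z_planes, dtype=float)
        if z.ndim != 1 or len(z) == 0 or np.any(np.diff(z) <= 0):
            raise ConfigurationError("z_planes must be strictly increasing")
        if self.psf_model not in ("wave_optics", "gaussian_defocus"):
            raise ConfigurationError(f"unknown psf_model {self.psf_model!r}")
        object.__setattr__(self, "z_planes", tuple(float(v) for v in z))

    @property
    def n_depths(self) -> int:
        return len(self.z_planes)

    @property
    def n_views(self) -> int:
        return self.pixels_per_lenslet ** 2

    def default_disparity_slope(self) -> float:
        """Lenslet disparity per μm of defocus per unit pixel offset.

        A marginal ray at angle sinθ = NA/n walks laterally by z·NA/n per μm
        of defocus; the pixel offset N/2 corresponds to that marginal angle,
        and one lenslet is ``lenslet_pitch`` μm wide.
        """
        if self.disparity_slope is not None:
            return float(self.disparity_slope)
        half = max(self.pixels_per_lenslet / 2.0, 0.5)
        return self.numerical_aperture / (
            self.medium_index * half * self.lenslet_pitch
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "OpticalConfig":
        return cls(**json.loads(text))


@dataclass
class Volume:
    """Non-negative 3D image stack (depth, height, width) with voxel size in μm."""

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data must be finite")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LightField:
    """Raw 2D light-field image; H and W must be divisible by N."""

    data: np.ndarray
    pixels_per_lenslet: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"LightField data must be 2D, got {self.data.shape}")
        h, w = self.data.shape
        n = self.pixels_per_lenslet
        if h % n or w % n:
            raise ValueError(
                f"light-field shape {self.data.shape} not divisible by N={n}"
            )

    @property
    def lenslet_grid(self):
        n = self.pixels_per_lenslet
        return (self.data.shape[0] // n, self.data.shape[1] // n)


@dataclass
class ViewStack:
    """The N² sub-aperture views, row-major over phase (i, j)."""

    data: np.ndarray
    pixels_per_lenslet: int
    view_order: str = "row-major (i, j)"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        n = self.pixels_per_lenslet
        if self.data.ndim != 3 or self.data.shape[0] != n * n:
            raise ValueError(
                f"ViewStack must have N²={n * n} views, got shape {self.data.shape}"
            )


@dataclass
class LightFieldPSF:
    """Kernel bank H[d, i, j, :, :]: sensor response of a unit point source.

    ``kernels[d, i, j][a, b]`` is the intensity at sensor pixel
    ``(ly*N - kh*N + a, lx*N - kh*N + b)`` for a unit source in lenslet
    ``(ly, lx)`` at depth ``z_planes[d]`` and phase ``(i, j)``.  Each
    (depth, phase) kernel carries unit mass, so projection conserves energy.
    """

    kernels: np.ndarray
    config: OpticalConfig

    def __post_init__(self):
        k = np.asarray(self.kernels, dtype=np.float64)
        n = self.config.pixels_per_lenslet
        d = self.config.n_depths
        s = (2 * self.config.kernel_halfwidth + 1) * n
        if k.shape != (d, n, n, s, s):
            raise ValueError(f"kernel bank shape {k.shape} != {(d, n, n, s, s)}")
        if not np.all(np.isfinite(k)) or np.any(k < 0):
            raise ValueError("kernels must be finite and non-negative")
        self.kernels = k

    @property
    def support(self) -> int:
        return self.kernels.shape[-1]

    def depth_mass(self, d: int) -> float:
        """Mean kernel mass over phases at depth d (1.0 when normalized)."""
        n = self.config.pixels_per_lenslet
        return float(self.kernels[d].sum() / (n * n))

    def lateral_rms_width(self, d: int) -> float:
        """Intensity-weighted lateral RMS radius of the depth-d kernel,
        averaged over source phases, in sensor pixels."""
        s = self.support
        yy, xx = np.mgrid[0:s, 0:s].astype(float)
        widths = []
        for i in range(self.config.pixels_per_lenslet):
            for j in range(self.config.pixels_per_lenslet):
                k = self.kernels[d, i, j]
                m = k.sum()
                if m <= 0:
                    continue
                cy = (k * yy).sum() / m
                cx = (k * xx).sum() / m
                r2 = (k * ((yy - cy) ** 2 + (xx - cx) ** 2)).sum() / m
                widths.append(np.sqrt(r2))
        return float(np.mean(widths))


# ----------------------------------------------------------------- PSF build


def _gaussian_defocus_kernel(cfg: OpticalConfig, z: float, i: int, j: int,
                             support: int) -> np.ndarray:
    n = cfg.pixels_per_lenslet
    kh = cfg.kernel_halfwidth
    c = (n - 1) / 2.0
    slope = cfg.default_disparity_slope()
    sigma_l = cfg.gauss_sigma0 + cfg.gauss_sigma_slope * abs(z)

    # sensor pixel (y, x) -> lenslet offset (Ly, Lx) and angular phase (a, b)
    pix = np.arange(support)
    lens = pix // n - kh          # lenslet offset from source lenslet
    phase = pix % n               # destination angular phase
    Ly = lens[:, None].astype(float)
    Lx = lens[None, :].astype(float)
    A = phase[:, None].astype(float)
    B = phase[None, :].astype(float)

    # sub-lenslet source position contributes a fractional lenslet shift
    dy0 = (i - c) / n
    dx0 = (j - c) / n
    # disparity of angular component (a, b) in lenslet units
    dy = slope * z * (A - c) + dy0
    dx = slope * z * (B - c) + dx0
    k = np.exp(-(((Ly - dy) ** 2) + ((Lx - dx) ** 2)) / (2.0 * sigma_l ** 2))
    return k


def _wave_optics_kernel_bank(cfg: OpticalConfig, support: int) -> np.ndarray:
    """Scalar-diffraction kernel bank (all depths and phases).

    Field of a defocused point source at the native image plane (pupil-limited
    angular spectrum with spherical defocus phase), multiplied by the tiled
    lenslet quadratic phase, Fresnel-propagated to the sensor over the lenslet
    focal distance f_l = pitch/(2·NA), then squared and binned to pixels.
    """
    n = cfg.pixels_per_lenslet
    d = cfg.n_depths
    over = 4  # oversampling per sensor pixel
    m = support * over
    dx = cfg.lenslet_pitch / n / over  # μm per sample, sample-referred
    lam = cfg.wavelength * 1e-3       # μm, vacuum
    na = cfg.numerical_aperture
    nmed = cfg.medium_index

    fx = np.fft.fftfreq(m, d=dx)
    FX, FY = np.meshgrid(fx, fx)
    F2 = FX ** 2 + FY ** 2
    f_max = na / lam
    pupil = (F2 <= f_max ** 2).astype(np.float64)
    # axial wavenumber in the medium (evanescent part suppressed by pupil)
    kz = (2 * np.pi / lam) * np.sqrt(
        np.maximum(nmed ** 2 - (lam ** 2) * F2, 0.0)
    )

    # lenslet phase mask, tiled
    f_l = cfg.lenslet_pitch / (2 * na)
    coords = (np.arange(m) - (m - 1) / 2.0) * dx
    local = (coords + cfg.lenslet_pitch / 2) % cfg.lenslet_pitch - cfg.lenslet_pitch / 2
    XX, YY = np.meshgrid(local, local)
    lens_phase = np.exp(-1j * np.pi * (XX ** 2 + YY ** 2) / (lam / nmed * f_l))

    # Fresnel propagation transfer function over f_l
    prop = np.exp(-1j * np.pi * (lam / nmed) * f_l * F2)

    bank = np.empty((d, n, n, support, support), dtype=np.float64)
    c = (n - 1) / 2.0
    for di, z in enumerate(cfg.z_planes):
        defocus = pupil * np.exp(1j * kz * z)
        for i in range(n):
            for j in range(n):
                # lateral source offset within the central lenslet
                uy = (i - c) * cfg.lenslet_pitch / n
                ux = (j - c) * cfg.lenslet_pitch / n
                tilt = np.exp(2j * np.pi * (FY * uy + FX * ux))
                field_native = np.fft.ifft2(defocus * tilt)
                field_native = np.fft.fftshift(field_native)
                field_sensor = np.fft.ifft2(
                    np.fft.fft2(field_native * lens_phase) * prop
                )
                inten = np.abs(field_sensor) ** 2
                binned = inten.reshape(support, over, support, over).sum(axis=(1, 3))
                bank[di, i, j] = binned
    return bank


def build_psf(config: OpticalConfig) -> LightFieldPSF:
    """Construct the light-field kernel bank for the configured model.

    Every (depth, phase) kernel is truncated at ``kernel_halfwidth`` lenslet
    pitches and renormalized to unit mass, so :func:`project` conserves energy.
    """
    n = config.pixels_per_lenslet
    support = (2 * config.kernel_halfwidth + 1) * n
    if config.psf_model == "wave_optics":
        bank = _wave_optics_kernel_bank(config, support)
    else:
        bank = np.empty((config.n_depths, n, n, support, support))
        for d, z in enumerate(config.z_planes):
            for i in range(n):
                for j in range(n):
                    bank[d, i, j] = _gaussian_defocus_kernel(config, z, i, j, support)
    mass = bank.sum(axis=(-2, -1), keepdims=True)
    if np.any(mass <= 0):
        raise ConfigurationError("degenerate PSF kernel with zero mass")
    bank = bank / mass
    return LightFieldPSF(kernels=bank, config=config)


# ---------------------------------------------------------------- projection


def _check_geometry(volume: Volume, psf: LightFieldPSF):
    cfg = psf.config
    n = cfg.pixels_per_lenslet
    dshape = volume.data.shape
    if dshape[0] != cfg.n_depths:
        raise ValueError(
            f"volume has {dshape[0]} depth planes but PSF expects {cfg.n_depths}"
        )
    if dshape[1] % n or dshape[2] % n:
        raise ValueError(
            f"volume lateral shape {dshape[1:]} not divisible by N={n}"
        )


def project(volume: Volume, psf: LightFieldPSF) -> LightField:
    """Forward-project a volume into a raw light-field image.

    Linear in the volume: each voxel at depth d and phase (i, j) stamps
    ``kernels[d, i, j]`` at its lenslet position (nearest-voxel placement,
    no interpolation).
    """
    _check_geometry(volume, psf)
    cfg = psf.config
    n = cfg.pixels_per_lenslet
    kh = cfg.kernel_halfwidth
    h, w = volume.data.shape[1:]
    out = np.zeros((h, w))
    pad = kh * n
    for d in range(cfg.n_depths):
        for i in range(n):
            for j in range(n):
                sub = volume.data[d, i::n, j::n]
                if not np.any(sub):
                    continue
                sparse = np.zeros((h, w))
                sparse[::n, ::n] = sub
                full = fftconvolve(sparse, psf.kernels[d, i, j], mode="full")
                out += full[pad:pad + h, pad:pad + w]
    np.maximum(out, 0.0, out=out)  # clip fft round-off
    return LightField(data=out, pixels_per_lenslet=n)


def project_adjoint(lf: LightField, psf: LightFieldPSF,
                    lateral_shape: tuple | None = None) -> Volume:
    """Adjoint Pᵀ of :func:`project` (back-projection onto the voxel grid)."""
    cfg = psf.config
    n = cfg.pixels_per_lenslet
    if lf.pixels_per_lenslet != n:
        raise ValueError(
            f"light field N={lf.pixels_per_lenslet} != PSF N={n}"
        )
    h, w = lf.data.shape
    if lateral_shape is None:
        lateral_shape = (h, w)
    kh = cfg.kernel_halfwidth
    pad = kh * n
    s = psf.support
    out = np.zeros((cfg.n_depths, *lateral_shape))
    g_full = np.zeros((h + s - 1, w + s - 1))
    g_full[pad:pad + h, pad:pad + w] = lf.data
    for d in range(cfg.n_depths):
        for i in range(n):
            for j in range(n):
                k = psf.kernels[d, i, j]
                corr = fftconvolve(g_full, k[::-1, ::-1], mode="valid")
                out[d, i::n, j::n] = corr[::n, ::n]
    return Volume(data=out)


# --------------------------------------------------------------------- views


def decompose_views(lf: LightField) -> ViewStack:
    """Rearrange a raw light field into its N² sub-aperture views.

    View ``(i, j)`` (row-major index ``i*N + j``) holds pixel ``(i, j)`` of
    every lenslet, preserving lenslet raster order.  Bit-exact inverse of
    :func:`recompose_views`.
    """
    n = lf.pixels_per_lenslet
    h, w = lf.data.shape
    gy, gx = h // n, w // n
    views = (
        lf.data.reshape(gy, n, gx, n)
        .transpose(1, 3, 0, 2)
        .reshape(n * n, gy, gx)
    )
    return ViewStack(data=views.copy(), pixels_per_lenslet=n)


def recompose_views(views: ViewStack) -> LightField:
    """Inverse of :func:`decompose_views` (exact)."""
    n = views.pixels_per_lenslet
    nv, gy, gx = views.data.shape
    if nv != n * n:
        raise ValueError(f"expected {n * n} views, got {nv}")
    lf = (
        views.data.reshape(n, n, gy, gx)
        .transpose(2, 0, 3, 1)
        .reshape(gy * n, gx * n)
    )
    return LightField(data=lf.copy(), pixels_per_lenslet=n)
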