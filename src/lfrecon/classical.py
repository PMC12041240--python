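"""Classical (non-learning) light-field reconstruction baselines.

* :func:`refocus` — synthetic-aperture shift-and-add: each sub-aperture view
  is shifted by its depth-dependent disparity and the views are averaged,
  one plane per requested depth.
* :func:`lfd_deconvolve` — light-field deconvolution: Richardson–Lucy
  iteration with the light-field kernel bank as the forward operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import shift as nd_shift

from .optics import (LightField, LightFieldPSF, OpticalConfig, Volume,
                     decompose_views, project, project_adjoint)


@dataclass
class ReconParams:
    """Parameters of the classical reconstructions.

    depths : refocus planes in μm (same axis as ``OpticalConfig.z_planes``).
    n_iterations : Richardson–Lucy iteration budget.
    stop_tolerance : relative-change early-stop threshold for RL.
    """

    depths: tuple = ()
    n_iterations: int = 30
    stop_tolerance: float = 0.0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def refocus(lf: LightField, config: OpticalConfig, params: ReconParams) -> Volume:
    """Shift-and-add refocusing over ``params.depths``.

    The disparity of view (i, j) at depth z is ``s·z·(i−c, j−c)`` lenslets,
    with c the central view index and s the slope derived from the optics
    (``OpticalConfig.default_disparity_slope``).  Views are shifted with
    linear interpolation and edge clamping, then averaged; the output stack
    is upsampled back to sensor resolution so it is comparable with other
    reconstructions.
    """
    depths = tuple(params.depths)
    if not depths:
        raise ValueError("refocus requires at least one depth")
    views = decompose_views(lf)
    n = config.pixels_per_lenslet
    c = (n - 1) / 2.0
    s = config.default_disparity_slope()
    gy, gx = views.data.shape[1:]
    # shift at sensor resolution so sub-lenslet disparities are multi-pixel
    # shifts (avoids interpolation washout of point images)
    up_views = np.repeat(np.repeat(views.data, n, axis=1), n, axis=2)
    stack = np.zeros((len(depths), gy * n, gx * n))
    for di, z in enumerate(depths):
        acc = np.zeros((gy * n, gx * n))
        for vi in range(n * n):
            i, j = divmod(vi, n)
            dy = -s * z * (i - c) * n
            dx = -s * z * (j - c) * n
            acc += nd_shift(up_views[vi], (dy, dx), order=1, mode="nearest")
        stack[di] = acc / (n * n)
    return Volume(data=stack)


def refocus_lowres(lf: LightField, config: OpticalConfig,
                   params: ReconParams) -> Volume:
    """Refocused stack at lenslet resolution (no upsampling)."""
    full = refocus(lf, config, params)
    n = config.pixels_per_lenslet
    return Volume(full.data[:, ::n, ::n].copy())


def lfd_deconvolve(lf: LightField, psf: LightFieldPSF, params: ReconParams,
                   history: list | None = None) -> Volume:
    """Richardson–Lucy light-field deconvolution.

    Multiplicative updates ``V ← V · Pᵀ(L / P(V)) / Pᵀ(1)`` with P the
    light-field projector; preserves non-negativity for a non-negative
    (here uniform positive) initialization.  Stops after ``n_iterations``
    or when the relative change drops below ``stop_tolerance``.  If a list
    is passed as ``history``, the per-iteration KL data-fit divergence is
    appended to it.
    """
    eps = 1e-12
    cfg = psf.config
    n = cfg.pixels_per_lenslet
    if lf.pixels_per_lenslet != n:
        raise ValueError(f"light field N={lf.pixels_per_lenslet} != PSF N={n}")
    h, w = lf.data.shape
    meas = np.maximum(lf.data, 0.0)
    v = Volume(np.full((cfg.n_depths, h, w), meas.mean() + eps))
    sens = project_adjoint(LightField(np.ones((h, w)), n), psf).data
    sens = np.maximum(sens, eps)
    prev = v.data
    for _ in range(params.n_iterations):
        fwd = project(v, psf).data
        if history is not None:
            m = (fwd > eps) & (meas > eps)
            kl = float(np.sum(meas[m] * np.log(meas[m] / fwd[m]) - meas[m] + fwd[m])
                       + np.sum(fwd[~m & (fwd > eps)]))
            history.append(kl)
        ratio = meas / np.maximum(fwd, eps)
        back = project_adjoint(LightField(ratio, n), psf).data
        new = v.data * back / sens
        change = np.abs(new - prev).sum() / max(prev.sum(), eps)
        v = Volume(new)
        if params.stop_tolerance > 0 and change < params.stop_tolerance:
            break
        prev = new
    return v
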