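"""Particle imaging velocimetry on reconstructed volumes.

3D particle localization (local maxima refined to intensity-weighted
centroids), the per-particle position-error tensor
sqrt(Σ_i (x_i − x_ideal_i)²), variational 3D optical flow (brightness
constancy + smoothness, Horn–Schunck-type fixed-point iteration with
coarse-to-fine warping), and velocity-error statistics against a reference
flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

from .optics import Volume
from .phantoms import FlowField, ParticleSet


@dataclass
class LocalizationResult:
    detected: ParticleSet
    errors: np.ndarray            # per matched pair, physical units
    mean_error: float
    n_unmatched_detected: int = 0
    n_unmatched_ideal: int = 0


@dataclass(frozen=True)
class FlowParams:
    """Horn–Schunck flow parameters: smoothness weight λ, fixed-point
    iterations per pyramid level, pyramid levels, warps per level."""

    regularization: float = 0.05
    n_iterations: int = 300
    pyramid_levels: int = 2
    n_warps: int = 4


def localize_particles(volume: Volume | np.ndarray, threshold: float = 0.3,
                       min_distance: int = 3,
                       refine_radius: int = 2) -> ParticleSet:
    """Detect particles as local maxima above ``threshold``·max, refined to
    intensity-weighted centroids over a ±``refine_radius`` voxel window.

    Positions are voxel coordinates (z, y, x); an empty volume yields an
    empty set.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, float)
    if data.max() <= 0:
        return ParticleSet(np.zeros((0, 3)), np.zeros(0))
    peaks = peak_local_max(data, min_distance=min_distance,
                           threshold_abs=threshold * data.max(),
                           exclude_border=False)
    if len(peaks) == 0:
        return ParticleSet(np.zeros((0, 3)), np.zeros(0))
    r = refine_radius
    centroids = np.empty((len(peaks), 3))
    for k, p in enumerate(peaks):
        lo = np.maximum(p - r, 0)
        hi = np.minimum(p + r + 1, data.shape)
        sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        base = sub - sub.min()
        m = base.sum()
        if m <= 0:
            centroids[k] = p
            continue
        idx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                          indexing="ij")
        centroids[k] = [float((base * ax).sum() / m) for ax in idx]
    return ParticleSet(centroids, np.zeros(len(peaks)))


def position_error(detected: ParticleSet, ideal: ParticleSet,
                   scale: np.ndarray | float = 1.0,
                   max_distance: float = np.inf) -> LocalizationResult:
    """Per-particle Euclidean position error after one-shot greedy
    nearest-neighbor matching.

    ``scale`` converts voxel coordinates to physical units per axis before
    the distance is taken; pairs farther than ``max_distance`` are counted
    as unmatched rather than scored.
    """
    sc = np.broadcast_to(np.asarray(scale, float), (3,))
    det = detected.positions * sc
    ide = ideal.positions * sc
    if len(det) == 0 or len(ide) == 0:
        return LocalizationResult(detected, np.zeros(0), float("nan"),
                                  len(det), len(ide))
    d2 = np.linalg.norm(det[:, None, :] - ide[None, :, :], axis=2)
    pairs = []
    used_d, used_i = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d2, axis=None), d2.shape))[0]
    for di, ii in order:
        if di in used_d or ii in used_i:
            continue
        if d2[di, ii] > max_distance:
            break
        used_d.add(di)
        used_i.add(ii)
        pairs.append(d2[di, ii])
    errors = np.array(pairs)
    mean = float(errors.mean()) if len(errors) else float("nan")
    return LocalizationResult(detected, errors, mean,
                              len(det) - len(pairs), len(ide) - len(pairs))


# -------------------------------------------------------------- optical flow


def _warp(vol: np.ndarray, flow: np.ndarray) -> np.ndarray:
    d, h, w = vol.shape
    grid = np.meshgrid(np.arange(d), np.arange(h), np.arange(w), indexing="ij")
    coords = [g + f for g, f in zip(grid, flow)]
    return ndi.map_coordinates(vol, coords, order=1, mode="nearest")


def _neighbor_average(u: np.ndarray) -> np.ndarray:
    """6-neighbor average with edge replication (Horn–Schunck ū)."""
    up = np.pad(u, 1, mode="edge")
    out = np.zeros_like(u)
    core = [slice(1, -1)] * u.ndim
    for ax in range(u.ndim):
        lo = core.copy(); lo[ax] = slice(0, -2)
        hi = core.copy(); hi[ax] = slice(2, None)
        out += up[tuple(lo)] + up[tuple(hi)]
    return out / (2 * u.ndim)


def _hs_level(v1: np.ndarray, v2: np.ndarray, flow: np.ndarray,
              params: FlowParams) -> np.ndarray:
    lam = params.regularization
    for _ in range(params.n_warps):
        v2w = _warp(v2, flow)
        grads = np.array(np.gradient(v2w))
        it = v2w - v1
        g2 = (grads ** 2).sum(axis=0)
        u = flow.copy()
        for _ in range(params.n_iterations):
            ubar = np.stack([_neighbor_average(u[c]) for c in range(3)])
            num = it + (grads * (ubar - flow)).sum(axis=0)
            u = ubar - grads * (num / (lam + g2))[None]
        flow = u
    return flow


def optical_flow_3d(vol1: Volume | np.ndarray, vol2: Volume | np.ndarray,
                    params: FlowParams = FlowParams()) -> FlowField:
    """Variational 3D optical flow from ``vol1`` to ``vol2``.

    Minimizes ∫(I_t + u·∇I)² + λ|∇u|² by Horn–Schunck fixed-point iteration,
    coarse-to-fine over a dyadic pyramid with intermediate warping.  Returns
    displacement in voxels/frame ordered (z, y, x).
    """
    a = vol1.data if isinstance(vol1, Volume) else np.asarray(vol1, float)
    b = vol2.data if isinstance(vol2, Volume) else np.asarray(vol2, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    scale = max(a.max(), b.max())
    if scale > 0:
        a, b = a / scale, b / scale
    if not np.any(np.gradient(a)) and not np.any(np.gradient(b)):
        return FlowField(np.zeros((3, *a.shape)))

    pyramids = [(a, b)]
    for _ in range(params.pyramid_levels - 1):
        pa, pb = pyramids[-1]
        if min(pa.shape) < 8:
            break
        pa = ndi.zoom(ndi.gaussian_filter(pa, 1.0), 0.5, order=1)
        pb = ndi.zoom(ndi.gaussian_filter(pb, 1.0), 0.5, order=1)
        pyramids.append((pa, pb))

    flow = np.zeros((3, *pyramids[-1][0].shape))
    for li in range(len(pyramids) - 1, -1, -1):
        pa, pb = pyramids[li]
        if flow.shape[1:] != pa.shape:
            zoom = np.array(pa.shape) / np.array(flow.shape[1:])
            flow = np.stack([ndi.zoom(flow[c], zoom, order=1) * zoom[c]
                             for c in range(3)])
        flow = _hs_level(pa, pb, flow, params)
    return FlowField(flow)


def velocity_error(est: FlowField, truth: FlowField,
                   mask: np.ndarray | None = None) -> dict:
    """Per-voxel |est − truth| magnitude error over ``mask``; returns the
    mean, standard error, and sample count."""
    if est.vectors.shape != truth.vectors.shape:
        raise ValueError(
            f"flow shape mismatch {est.vectors.shape} vs {truth.vectors.shape}")
    if mask is None:
        mask = np.ones(est.vectors.shape[1:], dtype=bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    diff = np.linalg.norm(est.vectors - truth.vectors, axis=0)[mask]
    n = int(diff.size)
    return {"mean": float(diff.mean()),
            "stderr": float(diff.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            "n": n,
            "per_voxel": diff}


def fit_solid_rotation(flow: FlowField, center=None, core_radius=None,
                       mask: np.ndarray | None = None) -> float:
    """Least-squares angular speed (rad/frame) of an x–z plane rotation
    fitted to a flow field; used to score vortex recovery."""
    v = flow.vectors
    _, d, h, w = v.shape
    z0 = (d - 1) / 2.0 if center is None else center[0]
    x0 = (w - 1) / 2.0 if center is None else center[1]
    zz, _, xx = np.meshgrid(np.arange(d, dtype=float), np.arange(h, dtype=float),
                            np.arange(w, dtype=float), indexing="ij")
    dz, dx = zz - z0, xx - x0
    r = np.sqrt(dz ** 2 + dx ** 2)
    sel = np.ones_like(r, bool) if core_radius is None else (r <= core_radius)
    sel &= r > 1e-9
    if mask is not None:
        sel &= mask
    # u_z = omega*dx, u_x = -omega*dz  ->  omega = (u_z·dx - u_x·dz)/(dx²+dz²)
    num = (v[0][sel] * dx[sel] - v[2][sel] * dz[sel]).sum()
    den = (dx[sel] ** 2 + dz[sel] ** 2).sum()
    return float(num / den)
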