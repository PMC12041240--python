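"""File I/O: TIFF volumes and light fields, HDF5 PSF banks, CSV particle
sets and traces, JSON reports.

Volumes are stored depth-major (one TIFF page per z-slice).  Metadata that
TIFF tags cannot carry reliably (voxel size, pixels-per-lenslet) goes into
the ImageDescription tag as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .optics import LightField, LightFieldPSF, OpticalConfig, Volume

_SUPPORTED_DTYPES = (np.uint8, np.uint16, np.float32, np.float64)


def _check_dtype(arr: np.ndarray, path):
    if arr.dtype.type not in _SUPPORTED_DTYPES:
        raise ValueError(
            f"unsupported dtype {arr.dtype} for {path}; use 8/16-bit integer "
            "or 32/64-bit float")


def write_volume(path, volume: Volume, dtype=np.float32):
    data = volume.data.astype(dtype)
    _check_dtype(data, path)
    meta = {"voxel_size": list(volume.voxel_size), "kind": "volume"}
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_volume(path) -> Volume:
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
    except Exception as exc:
        raise IOError(f"cannot read volume from {path}: {exc}") from exc
    voxel = (1.0, 1.0, 1.0)
    try:
        meta = json.loads(desc)
        voxel = tuple(meta.get("voxel_size", voxel))
    except (TypeError, ValueError):
        pass
    if data.ndim == 2:
        data = data[None]
    return Volume(np.asarray(data, dtype=np.float64), voxel)


def write_lightfield(path, lf: LightField, dtype=np.float32):
    data = lf.data.astype(dtype)
    _check_dtype(data, path)
    meta = {"pixels_per_lenslet": lf.pixels_per_lenslet, "kind": "lightfield"}
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_lightfield(path, pixels_per_lenslet: int | None = None) -> LightField:
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
    except Exception as exc:
        raise IOError(f"cannot read light field from {path}: {exc}") from exc
    n = pixels_per_lenslet
    try:
        meta = json.loads(desc)
        n = n or int(meta["pixels_per_lenslet"])
    except (TypeError, ValueError, KeyError):
        pass
    if n is None:
        raise ValueError(
            f"{path} carries no pixels_per_lenslet metadata; pass it explicitly")
    return LightField(np.asarray(data, dtype=np.float64), n)


def infer_max_i(path) -> float:
    """Dynamic-range ceiling from the stored sample format (255 for 8-bit,
    65535 for 16-bit, 1.0 for float)."""
    with tifffile.TiffFile(path) as tf:
        dt = tf.pages[0].dtype
    if dt == np.uint8:
        return 255.0
    if dt == np.uint16:
        return 65535.0
    return 1.0


def save_psf(path, psf: LightFieldPSF):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("kernels", data=psf.kernels, compression="gzip")
        f.attrs["config"] = psf.config.to_json()


def load_psf(path) -> LightFieldPSF:
    import h5py

    with h5py.File(path, "r") as f:
        cfg = OpticalConfig.from_json(f.attrs["config"])
        kernels = f["kernels"][()]
    return LightFieldPSF(kernels=kernels, config=cfg)


def write_particles_csv(path, particles, header="z,y,x,diameter"):
    pos = particles.positions
    dia = particles.diameters
    if len(dia) != len(pos):
        dia = np.zeros(len(pos))
    rows = np.column_stack([pos, dia])
    np.savetxt(path, rows, delimiter=",", header=header, comments="")


def read_particles_csv(path):
    from .phantoms import ParticleSet

    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if rows.size == 0:
        return ParticleSet(np.zeros((0, 3)), np.zeros(0))
    return ParticleSet(rows[:, :3], rows[:, 3] if rows.shape[1] > 3 else
                       np.zeros(len(rows)))


def write_traces_csv(path, traces):
    arr = np.stack([t.values for t in traces])
    header = "frame," + ",".join(f"neuron_{i}" for i in range(len(traces)))
    rows = np.column_stack([np.arange(arr.shape[1]), arr.T])
    np.savetxt(path, rows, delimiter=",", header=header, comments="")


def write_json(path, payload: dict):
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default)
                          + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")
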