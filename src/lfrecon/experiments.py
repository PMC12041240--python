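"""Desk-scale evaluation experiments.

Self-contained, seeded experiment recipes used by the acceptance checks and
the test suite: a toy GAN training run compared against the refocusing
baseline, the five-bead axial-localization comparison, the decorrelation
resolution probe, and the PIV flow-recovery probes.  Problem sizes are kept
small enough to run on one CPU in minutes; the methods note documents the
sizes used.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .classical import ReconParams, lfd_deconvolve, refocus
from .losses import LossConfig
from .metrics import decorrelation_kc, psnr
from .model import DiscriminatorSpec, GeneratorSpec
from .optics import OpticalConfig, Volume, build_psf, project
from .phantoms import ParticleSet, PhantomSpec, _rasterize_beads, make_beads, \
    make_particle_pair
from .piv import (FlowParams, fit_solid_rotation, localize_particles,
                  optical_flow_3d, position_error, velocity_error)
from .training import TrainConfig, predict, prepare_pair, train


def toy_optics(n: int = 4) -> OpticalConfig:
    """The N=4 desk-scale geometry used by the toy experiments."""
    return OpticalConfig(
        pixels_per_lenslet=n, z_planes=(-4.0, -2.0, 0.0, 2.0, 4.0),
        kernel_halfwidth=1, lenslet_pitch=1.0, numerical_aperture=1.0,
        medium_index=1.33, gauss_sigma0=0.3, gauss_sigma_slope=0.03,
        disparity_slope=0.12)


def toy_gan_experiment(seed: int = 1, n_steps: int = 200) -> dict:
    """Train the GAN on 8 bead-phantom pairs (16×16 views, 5 slices) for
    ``n_steps`` alternating steps and compare held-out reconstruction PSNR
    against the shift-and-add refocusing baseline.

    The desk-scale run uses larger learning rates (2e-3 / 2e-4) than the
    full-scale schedule because it spans a few hundred steps rather than
    hundreds of hours.
    """
    optics = toy_optics()
    psf = build_psf(optics)
    d, hw = 5, 64
    pairs, raws = [], []
    for s in range(9):
        vol, _ = make_beads(PhantomSpec(
            shape=(d, hw, hw), voxel_size=(1, 1, 1), seed=seed * 1000 + 100 + s,
            n_beads=6, bead_diameter=3.0, min_separation=8))
        lf = project(vol, psf)
        raws.append((lf, vol))
        pairs.append(prepare_pair(lf, vol))

    gspec = GeneratorSpec(n_views=16, view_size=(16, 16), out_slices=d,
                          upsample_factor=4, base_channels=16)
    dspec = DiscriminatorSpec(in_slices=d, n_blocks=3)
    loss_cfg = LossConfig(msssim_levels=2, berhu_reduction="mean")
    train_cfg = TrainConfig(epochs=(n_steps // 4) + 1, seed=seed,
                            max_steps=n_steps, batch_size=2,
                            lr_generator=2e-3, lr_discriminator=2e-4)
    gw, dw, hist = train(pairs[:8], gspec, dspec, loss_cfg, train_cfg)
    g = hist.series("g_total")

    lf_h, vol_h = raws[8]  # held-out phantom
    pred = predict(gw, lf_h)
    psnr_net, _ = psnr(pred.data, vol_h.data, 1.0)
    ref = refocus(lf_h, optics, ReconParams(depths=optics.z_planes))
    psnr_ref, _ = psnr(ref.data / ref.data.max(), vol_h.data, 1.0)
    return {
        "loss_first20": float(g[:20].mean()),
        "loss_last20": float(g[-20:].mean()),
        "psnr_net_db": psnr_net,
        "psnr_refocus_db": psnr_ref,
        "n_steps": int(len(g)),
        "history": hist,
    }


def bead_column_experiment(seed: int = 0) -> dict:
    """Five beads staggered in depth and x (the axial-localization probe):
    mean 3D position error of LFD vs refocusing against ground truth."""
    n, d = 4, 11
    zpl = tuple(np.linspace(-10, 10, d))
    optics = OpticalConfig(
        pixels_per_lenslet=n, z_planes=zpl, kernel_halfwidth=2,
        lenslet_pitch=1.0, numerical_aperture=1.0, medium_index=1.33,
        gauss_sigma0=0.3, gauss_sigma_slope=0.03, disparity_slope=0.1)
    psf = build_psf(optics)
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.3, 0.3, size=(5, 3))
    pos = np.stack([np.array([1.0, 3.0, 5.0, 7.0, 9.0]),
                    np.full(5, 32.0),
                    np.array([12.0, 22.0, 32.0, 42.0, 52.0])], axis=1) + jitter
    vol = _rasterize_beads((d, 64, 64), pos, np.full((5, 3), [0.7, 1.5, 1.5]))
    vol /= vol.max()
    truth = ParticleSet(pos, np.zeros(5))
    lf = project(Volume(vol), psf)

    rec_lfd = lfd_deconvolve(lf, psf, ReconParams(n_iterations=60))
    rec_ref = refocus(lf, optics, ReconParams(depths=zpl))
    out = {}
    for name, rec in (("lfd", rec_lfd), ("refocus", rec_ref)):
        det = localize_particles(rec, threshold=0.1, min_distance=3)
        res = position_error(det, truth, max_distance=10)
        out[f"err_{name}"] = res.mean_error
        out[f"matched_{name}"] = len(res.errors)
    return out


def decorrelation_experiment(seed: int = 0, kc_true: float = 0.3) -> dict:
    """Recover an imposed radial band-limit with decorrelation analysis."""
    rng = np.random.default_rng(seed)
    img = rng.standard_normal((256, 256))
    F = np.fft.fft2(img)
    f = np.fft.fftfreq(256) * 2
    R = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    band = np.real(np.fft.ifft2(F * (R <= kc_true)))
    return {
        "kc_bandlimited": decorrelation_kc(band),
        "kc_true": kc_true,
        "kc_white_noise": decorrelation_kc(rng.standard_normal((256, 256))),
    }


def flow_experiments(seed: int = 0) -> dict:
    """PIV probes: zero flow on identical volumes, unit axial shift, and
    solid-body vortex angular-speed recovery."""
    vol, _ = make_beads(PhantomSpec(
        shape=(16, 48, 48), voxel_size=(1, 1, 1), seed=seed + 70, n_beads=25,
        bead_diameter=4.0, min_separation=4))
    zero = optical_flow_3d(vol, vol)

    a = ndi.gaussian_filter(vol.data, 0.5)
    b = np.roll(a, 1, axis=0)
    f = optical_flow_3d(a, b)
    interior = np.s_[3:-3, 3:-3, 3:-3]
    w = a[interior] > 0.05
    shift_est = float(f.vectors[0][interior][w].mean())

    spec = PhantomSpec(shape=(24, 24, 48), voxel_size=(1, 1, 1), seed=seed + 90,
                       particles_per_lenslet=0.4, pixels_per_lenslet=4,
                       particle_diameter=4.0, flow="vortex", vortex_omega=0.08)
    v1, v2, _, _, truth = make_particle_pair(spec)
    fest = optical_flow_3d(v1, v2)
    d, h, wd = spec.shape
    zz, _, xx = np.meshgrid(np.arange(d, dtype=float), np.arange(h, dtype=float),
                            np.arange(wd, dtype=float), indexing="ij")
    r = np.sqrt((zz - (d - 1) / 2) ** 2 + (xx - (wd - 1) / 2) ** 2)
    mask = (v1.data > 0.05) & (r > 2) & (r < 10)
    omega = fit_solid_rotation(fest, mask=mask)
    verr = velocity_error(fest, truth, mask)
    return {
        "zero_flow_max": float(np.abs(zero.vectors).max()),
        "unit_shift_estimate": shift_est,
        "vortex_omega_true": spec.vortex_omega,
        "vortex_omega_estimate": omega,
        "vortex_velocity_error_mean": verr["mean"],
        "vortex_velocity_error_n": verr["n"],
    }
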