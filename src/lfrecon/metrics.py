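"""Quantitative evaluation metrics for reconstructed images and volumes.

PSNR, SSIM (global-statistics form, optional sliding window), MS-SSIM,
LPIPS-style perceptual distance with a pluggable feature extractor, MSE and
Pearson correlation; plus decorrelation-based resolution estimation,
full-width-at-half-maximum measurement, and ΔF/F₀ calcium-trace extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .losses import LossConfig, msssim

PSNR_CAP_DB = 99.0


@dataclass
class MetricReport:
    psnr: float
    ssim: float
    msssim: float
    lpips: float
    mse: float
    pearson: float
    psnr_capped: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("psnr", "ssim", "msssim", "lpips", "mse", "pearson",
                 "psnr_capped")}


@dataclass(frozen=True)
class FeatureExtractorConfig:
    """LPIPS feature stack: a seeded random convolutional pyramid by default
    (deterministic and self-contained); layer weights are unit by default."""

    backbone: str = "fixed_random"
    n_layers: int = 3
    channels: tuple = (8, 16, 32)
    layer_weights: tuple = (1.0, 1.0, 1.0)
    seed: int = 0


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error between same-shape arrays."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return float(np.mean((y - x) ** 2))


def psnr(x: np.ndarray, y: np.ndarray, max_i: float = 1.0) -> tuple[float, bool]:
    """Peak signal-to-noise ratio 10·log10(MAX²/MSE) in dB.

    Identical inputs are reported as the 99 dB sentinel with a flag rather
    than +∞ so reports stay serializable."""
    m = mse(x, y)
    if m == 0.0:
        return PSNR_CAP_DB, True
    val = 10.0 * np.log10(max_i ** 2 / m)
    return float(min(val, PSNR_CAP_DB)), bool(val > PSNR_CAP_DB)


def ssim_global(x: np.ndarray, y: np.ndarray, dynamic_range: float = 1.0) -> float:
    """Structural similarity from global image statistics:
    (2μxμy+C1)(2σxy+C2) / ((μx²+μy²+C1)(σx²+σy²+C2)),
    C1=(0.01R)², C2=(0.03R)²."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float((2 * mx * my + c1) * (2 * cov + c2)
                 / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))


def ssim_windowed(x: np.ndarray, y: np.ndarray, dynamic_range: float = 1.0,
                  window: int = 7) -> float:
    """Sliding-uniform-window SSIM map, averaged (2D inputs)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    mx = uniform_filter(x, window)
    my = uniform_filter(y, window)
    vx = uniform_filter(x * x, window) - mx ** 2
    vy = uniform_filter(y * y, window) - my ** 2
    cov = uniform_filter(x * y, window) - mx * my
    m = ((2 * mx * my + c1) * (2 * cov + c2)
         / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    return float(m.mean())


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation ρ = E[(X−μx)(Y−μy)]/(σxσy)."""
    x, y = np.asarray(x, float).ravel(), np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


# ------------------------------------------------------------------- LPIPS


def _feature_stack(img: np.ndarray, cfg: FeatureExtractorConfig):
    """Seeded random conv pyramid with stride 2 and ReLU; features are
    channel-unit-normalized per pixel, as perceptual metrics do."""
    rng = np.random.default_rng(cfg.seed)
    x = img[None, None] if img.ndim == 2 else img[None]
    feats = []
    c_in = x.shape[1]
    for li in range(cfg.n_layers):
        c_out = cfg.channels[li % len(cfg.channels)]
        w = rng.normal(0, np.sqrt(2.0 / (c_in * 9)), (c_out, c_in, 3, 3))
        b, c, h, ww = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        s0, s1, s2, s3 = xp.strides
        oh, ow = (h - 1) // 2 + 1, (ww - 1) // 2 + 1
        cols = np.lib.stride_tricks.as_strided(
            xp, (b, c, 3, 3, oh, ow), (s0, s1, s2, s3, s2 * 2, s3 * 2))
        x = np.maximum(np.einsum("ockl,bcklhw->bohw", w, cols, optimize=True), 0)
        norm = np.sqrt((x ** 2).sum(axis=1, keepdims=True)) + 1e-10
        feats.append(x / norm)
        c_in = x.shape[1]
    return feats


def lpips(x: np.ndarray, y: np.ndarray,
          cfg: FeatureExtractorConfig = FeatureExtractorConfig()) -> float:
    """Perceptual distance: Σ_l mean_hw ||w_l ⊙ (F_l(x) − F_l(y))||² over the
    configured feature stack.  Non-negative, symmetric, zero iff the feature
    maps agree; absolute values depend on the backbone."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if x.ndim == 3:  # volume: score per slice, average
        return float(np.mean([lpips(xs, ys, cfg) for xs, ys in zip(x, y)]))
    fx = _feature_stack(x, cfg)
    fy = _feature_stack(y, cfg)
    total = 0.0
    for li, (a, b) in enumerate(zip(fx, fy)):
        wl = cfg.layer_weights[li % len(cfg.layer_weights)]
        d = (wl * (a - b)) ** 2
        total += float(d.sum(axis=1).mean())
    return total


def compute_metrics(x, y, max_i: float = 1.0,
                    loss_cfg: LossConfig | None = None,
                    feature_cfg: FeatureExtractorConfig = FeatureExtractorConfig(),
                    ssim_mode: str = "global") -> MetricReport:
    """All six fidelity metrics between a reconstruction ``x`` and ground
    truth ``y`` (arrays or Volumes of equal shape)."""
    x = getattr(x, "data", x)
    y = getattr(y, "data", y)
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if loss_cfg is None:
        # pick the deepest dyadic pyramid the lateral size allows (max 5)
        short = min(x.shape[-2:])
        levels = max(1, min(5, int(np.floor(np.log2(short / 11))) + 1))
        loss_cfg = LossConfig(msssim_levels=levels, dynamic_range=max_i)
    p, capped = psnr(x, y, max_i)
    if ssim_mode == "global":
        s = ssim_global(x, y, max_i)
    else:
        s = (ssim_windowed(x, y, max_i) if x.ndim == 2 else
             float(np.mean([ssim_windowed(a, b, max_i) for a, b in zip(x, y)])))
    return MetricReport(
        psnr=p, ssim=s, msssim=float(msssim(x, y, loss_cfg)),
        lpips=lpips(x, y, feature_cfg), mse=mse(x, y),
        pearson=pearson(x, y), psnr_capped=capped)


# --------------------------------------------------- resolution estimation


def decorrelation_kc(image: np.ndarray, n_filters: int = 10,
                     n_radii: int = 50) -> float:
    """Decorrelation-based cut-off frequency, normalized to Nyquist = 1.

    The normalized spectrum is cross-correlated with radially masked copies
    of the raw spectrum over a series of mask radii; repeating this for a
    series of Gaussian high-pass filtered images (weak to strong) yields a
    family of decorrelation curves, and the cut-off is the radius of the
    highest local correlation peak across the family.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("decorrelation_kc expects a 2D image")
    if img.max() == img.min():
        raise ValueError("decorrelation undefined for a constant image")
    img = img - img.mean()
    h, w = img.shape
    win = (np.hanning(h)[:, None] * np.hanning(w)[None, :])
    F = np.fft.fftshift(np.fft.fft2(img * win))
    fy = np.fft.fftshift(np.fft.fftfreq(h)) * 2  # Nyquist -> 1
    fx = np.fft.fftshift(np.fft.fftfreq(w)) * 2
    R = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)

    radii = np.linspace(0.02, 1.0, n_radii)
    # high-pass series: remove an increasing low-frequency core
    sigmas = np.concatenate([[0.0], np.geomspace(0.08, 0.8, n_filters)])

    best_kc, best_amp = 0.0, -np.inf
    absF = np.abs(F)
    for sg in sigmas:
        if sg == 0.0:
            Ff = F
        else:
            Ff = F * (1.0 - np.exp(-(R ** 2) / (2 * sg ** 2)))
        mag = np.abs(Ff)
        normF = np.where(mag > 0, Ff / np.maximum(mag, 1e-30), 0.0)
        d = np.empty(n_radii)
        denom_full = np.sqrt((np.abs(Ff) ** 2).sum())
        for ri, r in enumerate(radii):
            mask = R <= r
            num = np.real(np.vdot(Ff[mask], normF[mask]))
            den = denom_full * np.sqrt((np.abs(normF[mask]) ** 2).sum())
            d[ri] = num / den if den > 0 else 0.0
        # highest maximum of this decorrelation curve; interior maxima are
        # refined parabolically, an end-of-curve maximum is taken as-is
        ri = int(np.argmax(d))
        pk_amp, pk_r = d[ri], radii[ri]
        if 0 < ri < n_radii - 1:
            denom = d[ri - 1] - 2 * d[ri] + d[ri + 1]
            off = 0.5 * (d[ri - 1] - d[ri + 1]) / denom if denom != 0 else 0.0
            pk_r = radii[ri] + np.clip(off, -0.5, 0.5) * (radii[1] - radii[0])
        if pk_amp > best_amp and pk_r > 0:
            best_amp, best_kc = pk_amp, pk_r
    return float(np.clip(best_kc, 0.0, 1.0))


def fwhm_profile(profile: np.ndarray, sample_spacing: float = 1.0) -> float:
    """Full width at half maximum of a single-peaked 1D profile, by linear
    interpolation of the half-level crossings above the boundary baseline."""
    p = np.asarray(profile, float)
    if p.ndim != 1 or p.size < 3:
        raise ValueError("profile must be 1D with at least 3 samples")
    imax = int(np.argmax(p))
    baseline = float(p.min())
    peak = float(p[imax])
    if imax == 0 or imax == p.size - 1 or peak <= baseline:
        raise ValueError("profile has no interior maximum above its baseline")
    half = baseline + 0.5 * (peak - baseline)
    li = imax
    while li > 0 and p[li] > half:
        li -= 1
    if p[li] > half:
        raise ValueError("no left half-maximum crossing")
    ri = imax
    while ri < p.size - 1 and p[ri] > half:
        ri += 1
    if p[ri] > half:
        raise ValueError("no right half-maximum crossing")
    # sub-sample crossings from a cubic-spline model of the profile
    # (reduces to linear interpolation on piecewise-linear profiles)
    from scipy.interpolate import CubicSpline

    xs = np.arange(p.size, dtype=float)
    spl = CubicSpline(xs, p - half)
    left = _spline_root(spl, li, li + 1)
    right = _spline_root(spl, ri - 1, ri)
    return float((right - left) * sample_spacing)


def _spline_root(spl, lo, hi):
    """Root of a cubic spline within [lo, hi] by bisection."""
    a, b = float(lo), float(hi)
    fa, fb = spl(a), spl(b)
    if fa == 0:
        return a
    if fb == 0:
        return b
    if fa * fb > 0:  # spline overshoot: fall back to the linear crossing
        return a + fa / (fa - fb) * (b - a)
    for _ in range(60):
        m = 0.5 * (a + b)
        fm = spl(m)
        if fa * fm <= 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


def dff_traces(roi_means: np.ndarray) -> np.ndarray:
    """ΔF/F₀ per neuron: (F − F₀)/F₀ with F₀ the time-average of F.

    ``roi_means`` is (n_neurons, n_frames) of per-frame ROI mean
    fluorescence (a single trace may be passed as 1D)."""
    f = np.atleast_2d(np.asarray(roi_means, float))
    if not np.all(np.isfinite(f)):
        raise ValueError("fluorescence traces must be finite")
    f0 = f.mean(axis=1, keepdims=True)
    if np.any(f0 == 0):
        raise ValueError("zero baseline F0; cannot form ΔF/F0")
    out = (f - f0) / f0
    return out[0] if np.asarray(roi_means).ndim == 1 else out


def roi_means_from_frames(frames: np.ndarray, masks) -> np.ndarray:
    """Per-frame mean fluorescence inside each ROI mask of a (T, ...) stack."""
    t = frames.shape[0]
    out = np.empty((len(masks), t))
    for mi, m in enumerate(masks):
        flat = frames.reshape(t, -1)[:, np.asarray(m).ravel()]
        out[mi] = flat.mean(axis=1)
    return out
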