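"""The composite training objective of the view-to-volume GAN.

Total generator loss:  α·BerHu + β·(1 − MS-SSIM) + γ·BCE(D(G(x)), 1),
with α = 3, β = 1, γ = 0.5 by default.  BerHu is the reverse Huber
(L1 inside a threshold c, scaled quadratic outside, c = 0.1); MS-SSIM is the
multi-scale structural similarity with the standard exponents; the
adversarial term is the non-saturating generator BCE, with the discriminator
objective ½·log(1 − D(G(x))) + ½·log D(y) to be maximized.

All losses accept plain arrays (returning floats) or autodiff tensors
(returning tensors), so the same code scores images and trains the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.autograd import Tensor, avg_pool2d, depthwise_conv2d_fixed

EPS_LOG = 1e-7

# standard MS-SSIM scale exponents (5 dyadic scales)
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass(frozen=True)
class LossConfig:
    """Weights and constants of the composite objective.

    alpha/beta/gamma weight BerHu, MS-SSIM loss, and the adversarial term;
    berhu_c is the reverse-Huber threshold; msssim_* configure the
    similarity (dyadic levels, per-scale exponents, stability constants
    derived from the dynamic range R, and the Gaussian statistics window).
    """

    alpha: float = 3.0
    beta: float = 1.0
    gamma: float = 0.5
    berhu_c: float = 0.1
    berhu_reduction: str = "sum"          # printed form; "mean" for training
    msssim_levels: int = 5
    msssim_weights: tuple = MSSSIM_WEIGHTS
    dynamic_range: float = 1.0
    msssim_window: int = 11
    msssim_sigma: float = 1.5

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.berhu_c <= 0:
            raise ValueError("berhu_c must be > 0")
        if self.msssim_levels < 1:
            raise ValueError("msssim_levels must be >= 1")

    @property
    def c1(self) -> float:
        return (0.01 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (0.03 * self.dynamic_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


def _is_tensor(*xs):
    return any(isinstance(x, Tensor) for x in xs)


def _coerce(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def berhu(pred, target, c: float = 0.1, reduction: str = "sum"):
    """Reverse Huber: |d| for |d| ≤ c, (d² + c²)/(2c) for |d| > c.

    Continuous at |d| = c (both branches equal c).  ``reduction`` is the
    printed per-pixel sum by default; "mean" divides by the element count.
    """
    if c <= 0:
        raise ValueError("berhu threshold c must be > 0")
    tensor_mode = _is_tensor(pred, target)
    p, t = _coerce(pred), _coerce(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    d = p - t
    absd = d.abs()
    mask = Tensor((absd.data > c).astype(float))
    small = absd * (1.0 - mask)
    big = ((d * d) + c * c) * (1.0 / (2.0 * c)) * mask
    out = (small + big).sum()
    if reduction == "mean":
        out = out * (1.0 / d.data.size)
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return out if tensor_mode else out.item()


def _gauss_window(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    w = np.outer(g, g)
    return w / w.sum()


def _as_bchw(x: Tensor) -> Tensor:
    if len(x.shape) == 2:
        return x.reshape(1, 1, *x.shape)
    if len(x.shape) == 3:  # (slices, H, W): score each slice, average
        return x.reshape(1, *x.shape)
    return x


def msssim(pred, target, cfg: LossConfig = LossConfig()):
    """Multi-scale structural similarity in [0, 1] (for non-negative inputs).

    Per dyadic scale j the contrast and structure terms are computed from
    Gaussian-window local statistics and averaged over space; the luminance
    term enters at the coarsest scale only.  Scales are linked by 2×
    average-pool downsampling.  Exponents default to the standard constants.
    """
    tensor_mode = _is_tensor(pred, target)
    x, y = _as_bchw(_coerce(pred)), _as_bchw(_coerce(target))
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    M = cfg.msssim_levels
    win = cfg.msssim_window
    if min(x.shape[2], x.shape[3]) < win * 2 ** (M - 1) / 2 + 1 or \
            min(x.shape[2], x.shape[3]) // 2 ** (M - 1) < win:
        raise ValueError(
            f"image of lateral size {x.shape[2:]} too small for {M} dyadic "
            f"scales with a {win}-pixel window; reduce msssim_levels")
    weights = np.asarray(cfg.msssim_weights[:M], dtype=float)
    weights = weights / weights.sum()
    kernel = _gauss_window(win, cfg.msssim_sigma)
    c1, c2, c3 = cfg.c1, cfg.c2, cfg.c3

    total = None
    for j in range(M):
        mu_x = depthwise_conv2d_fixed(x, kernel)
        mu_y = depthwise_conv2d_fixed(y, kernel)
        var_x = (depthwise_conv2d_fixed(x * x, kernel) - mu_x * mu_x).clamp_min(0.0)
        var_y = (depthwise_conv2d_fixed(y * y, kernel) - mu_y * mu_y).clamp_min(0.0)
        cov = depthwise_conv2d_fixed(x * y, kernel) - mu_x * mu_y
        sx, sy = var_x.sqrt(), var_y.sqrt()
        contrast = ((sx * sy * 2.0 + c2) / (var_x + var_y + c2)).mean()
        structure = ((cov + c3) / (sx * sy + c3)).mean()
        term = (contrast.clamp_min(EPS_LOG) ** float(weights[j])
                * structure.clamp_min(EPS_LOG) ** float(weights[j]))
        total = term if total is None else total * term
        if j == M - 1:
            lum = ((mu_x * mu_y * 2.0 + c1)
                   / (mu_x * mu_x + mu_y * mu_y + c1)).mean()
            total = total * lum.clamp_min(EPS_LOG) ** float(weights[j])
        else:
            x, y = avg_pool2d(x, 2), avg_pool2d(y, 2)
    return total if tensor_mode else total.item()


def msssim_loss(pred, target, cfg: LossConfig = LossConfig()):
    """1 − MS-SSIM (the similarity itself is not a loss)."""
    s = msssim(pred, target, cfg)
    return (1.0 - s) if isinstance(s, float) else (1.0 - s)


def adversarial_losses(d_real, d_fake):
    """Discriminator objective and generator BCE.

    d_objective = ½·log(1 − D(G(x))) + ½·log D(y), to be *maximized* by the
    discriminator (its supremum is 0); g_bce = −log D(G(x)), the
    non-saturating generator term driving D(G(x)) toward 1.  Scores at exact
    0/1 are clamped by ε = 1e-7.
    """
    tensor_mode = _is_tensor(d_real, d_fake)
    dr, df = _coerce(d_real), _coerce(d_fake)
    dr_c = dr.clamp_min(EPS_LOG)
    one_minus_df = (1.0 - df).clamp_min(EPS_LOG)
    df_c = df.clamp_min(EPS_LOG)
    d_obj = (one_minus_df.log().mean() + dr_c.log().mean()) * 0.5
    g_bce = -(df_c.log().mean())
    if tensor_mode:
        return d_obj, g_bce
    return d_obj.item(), g_bce.item()


def combine_losses(berhu_val, msssim_loss_val, g_bce_val,
                   cfg: LossConfig = LossConfig()):
    """Weighted sum α·BerHu + β·(1−MS-SSIM) + γ·BCE of precomputed terms."""
    return (cfg.alpha * berhu_val + cfg.beta * msssim_loss_val
            + cfg.gamma * g_bce_val)


def total_generator_loss(pred, target, d_fake, cfg: LossConfig = LossConfig()):
    """Full generator objective on prediction/target plus discriminator score."""
    b = berhu(pred, target, cfg.berhu_c, reduction=cfg.berhu_reduction)
    m = msssim_loss(pred, target, cfg)
    _, g = adversarial_losses(0.5, d_fake) if not _is_tensor(d_fake) else \
        adversarial_losses(Tensor(np.array(0.5)), d_fake)
    return combine_losses(b, m, g, cfg)


def normalize_unit(x: np.ndarray) -> np.ndarray:
    """Affine map of an array onto [−1, 1]: 2·(x − min)/(max − min) − 1."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("cannot normalize a constant input to [-1, 1]")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def denormalize_unit(x: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Inverse of :func:`normalize_unit` onto the range [lo, hi]."""
    return (np.asarray(x, dtype=float) + 1.0) / 2.0 * (hi - lo) + lo
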