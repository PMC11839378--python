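"""Image-comparison metric suite: mean ± std, ℓ1, ℓ2, NCC, and SSIM.

All metrics operate on max-normalized envelope images (values in [0, 1]).
With ground truth x and network output y over N overlapping pixels:

    ℓ1 = (1/N) Σ |xₙ − yₙ|
    ℓ2 = (1/N) Σ (xₙ − yₙ)²
    NCC = Σ (xₙ−μx)(yₙ−μy) / sqrt(Σ(xₙ−μx)² · Σ(yₙ−μy)²)
    SSIM = (2μxμy + C1)(2σxy + C2) / ((μx²+μy²+C1)(σx²+σy²+C2))

with C1 = (k1·L)², C2 = (k2·L)² regularizers on the luminance and
contrast/structure terms.  The population (1/N) variance convention is used
throughout, matching the 1/N normalization of the ℓ losses.  SSIM defaults
to the standard windowed form (11×11 Gaussian weights, σ = 1.5) averaged
over all fully-interior windows; a ``global`` mode evaluates the formula
once over the whole image.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import correlate1d

from .acquisition import EnvelopeImage
from .errors import ValidationError, ZeroVarianceError

__all__ = [
    "MetricConfig",
    "MetricReport",
    "image_mean_std",
    "l1_loss",
    "l2_loss",
    "ncc",
    "ssim",
    "compute_report",
]


@dataclass(frozen=True)
class MetricConfig:
    """SSIM regularizers and windowing.

    ``ssim_L`` is the dynamic range of the compared images (1.0 for
    normalized envelopes).  ``window`` must be odd; ``sigma`` is the Gaussian
    weight spread in pixels.
    """

    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    ssim_L: float = 1.0
    ssim_mode: Literal["windowed", "global"] = "windowed"
    window: int = 11
    sigma: float = 1.5

    def __post_init__(self):
        if self.ssim_k1 <= 0 or self.ssim_k2 <= 0 or self.ssim_L <= 0:
            raise ValidationError("k1, k2, L must be positive")
        if self.window % 2 == 0 or self.window < 1:
            raise ValidationError("window size must be odd and >= 1")
        if self.ssim_mode not in ("windowed", "global"):
            raise ValidationError(f"unknown ssim_mode {self.ssim_mode!r}")

    @property
    def c1(self) -> float:
        return (self.ssim_k1 * self.ssim_L) ** 2

    @property
    def c2(self) -> float:
        return (self.ssim_k2 * self.ssim_L) ** 2


@dataclass(frozen=True)
class MetricReport:
    """Full metric suite for one (ground truth, network output) pair."""

    mean: float
    std: float
    l1: float
    l2: float
    ncc: float
    ssim: float
    n_pixels: int

    def to_dict(self) -> dict:
        return asdict(self)


def _values(img) -> np.ndarray:
    v = img.values if isinstance(img, EnvelopeImage) else np.asarray(img, dtype=np.float64)
    if v.size == 0:
        raise ValidationError("empty image")
    return v


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xv, yv = _values(x), _values(y)
    if xv.shape != yv.shape:
        raise ValidationError(
            f"image shapes differ: {xv.shape} vs {yv.shape} (no implicit resampling)"
        )
    return xv, yv


def image_mean_std(img) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation over all pixels."""
    v = _values(img)
    return float(v.mean()), float(v.std())


def l1_loss(x, y) -> float:
    """Mean absolute difference (1/N)·Σ|xₙ − yₙ|."""
    xv, yv = _pair(x, y)
    return float(np.abs(xv - yv).mean())


def l2_loss(x, y) -> float:
    """Mean squared difference (1/N)·Σ(xₙ − yₙ)²."""
    xv, yv = _pair(x, y)
    return float(((xv - yv) ** 2).mean())


def ncc(x, y) -> float:
    """Normalized cross correlation (Pearson correlation of the pixel values).

    Invariant under positive affine maps of either argument.  Zero-variance
    input raises :class:`ZeroVarianceError` rather than returning NaN, since
    a constant image usually signals a degenerate beamformer output.
    """
    xv, yv = _pair(x, y)
    dx = xv - xv.mean()
    dy = yv - yv.mean()
    sx = float((dx**2).sum())
    sy = float((dy**2).sum())
    if sx <= 0 or sy <= 0:
        raise ZeroVarianceError(
            "correlation undefined: at least one image has zero variance"
        )
    return float(np.clip((dx * dy).sum() / np.sqrt(sx * sy), -1.0, 1.0))


def _gauss_kernel(window: int, sigma: float) -> np.ndarray:
    r = np.arange(window) - window // 2
    k = np.exp(-(r**2) / (2.0 * sigma**2))
    return k / k.sum()


def _win_filter(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Separable weighted mean over fully-interior windows (borders cropped)."""
    out = correlate1d(img, kernel, axis=0, mode="constant")
    out = correlate1d(out, kernel, axis=1, mode="constant")
    pad = kernel.size // 2
    if pad:
        out = out[pad:-pad, pad:-pad]
    return out


def ssim(x, y, cfg: MetricConfig | None = None) -> float:
    """Structural similarity between two images in [0, L].

    Windowed mode returns the mean of the SSIM map over Gaussian-weighted
    windows fully inside the image; global mode evaluates the collapsed
    formula once with whole-image population statistics.
    """
    cfg = cfg or MetricConfig()
    xv, yv = _pair(x, y)
    c1, c2 = cfg.c1, cfg.c2
    if cfg.ssim_mode == "global":
        mx, my = xv.mean(), yv.mean()
        vx = ((xv - mx) ** 2).mean()
        vy = ((yv - my) ** 2).mean()
        cov = ((xv - mx) * (yv - my)).mean()
        val = ((2 * mx * my + c1) * (2 * cov + c2)) / (
            (mx**2 + my**2 + c1) * (vx + vy + c2)
        )
        return float(val)
    if cfg.window > min(xv.shape):
        raise ValidationError(
            f"SSIM window {cfg.window} exceeds image extent {min(xv.shape)}"
        )
    k = _gauss_kernel(cfg.window, cfg.sigma)
    mx = _win_filter(xv, k)
    my = _win_filter(yv, k)
    vx = _win_filter(xv * xv, k) - mx**2
    vy = _win_filter(yv * yv, k) - my**2
    cov = _win_filter(xv * yv, k) - mx * my
    ssim_map = ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )
    return float(ssim_map.mean())


def compute_report(x, y, cfg: MetricConfig | None = None) -> MetricReport:
    """All metrics for one pair; ``mean``/``std`` describe the output y."""
    xv, yv = _pair(x, y)
    m, s = image_mean_std(yv)
    return MetricReport(
        mean=m,
        std=s,
        l1=l1_loss(xv, yv),
        l2=l2_loss(xv, yv),
        ncc=ncc(xv, yv),
        ssim=ssim(xv, yv, cfg),
        n_pixels=int(xv.size),
    )
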