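"""Image-quality metrics for generated vs. ground-truth EVG images.

MSE/RMSE/PSNR over all pixels and channels, a per-channel-averaged SSIM
computed from *global* image statistics (mean, standard deviation and
cross-covariance of each channel — not the common 11x11 windowed
variant, which is available behind a flag), and an RMSE restricted to
the fibrous regions. Fibrous pixels are found by HSV thresholding of the
EVG rendering with two ranges: deep-blue-to-pink (elastic and collagen)
and dark near-black variants (heavily stained elastic). Hue uses the
0-179 integer convention, saturation and value 0-255.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "SSIMParams",
    "HSVRange",
    "MetricsRecord",
    "DEFAULT_FIBROUS_RANGES",
    "mse_rmse",
    "psnr",
    "ssim_rgb",
    "fibrous_mask",
    "fibrous_rmse",
    "evaluate_pair",
    "dataset_report",
]

PSNR_INF_SENTINEL = float("inf")


@dataclass(frozen=True)
class SSIMParams:
    """Exponents and stabilising constants of the SSIM formula.

    ``C1 = (0.01 L)**2``, ``C2 = (0.03 L)**2``, ``C3 = C2 / 2`` with
    dynamic range ``L`` (255 for 8-bit images); unit exponents by default.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma_exp: float = 1.0
    L: float = 255.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma_exp) <= 0:
            raise ValueError("SSIM exponents must be positive")

    @property
    def C1(self) -> float:
        return (0.01 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (0.03 * self.L) ** 2

    @property
    def C3(self) -> float:
        return self.C2 / 2.0


@dataclass(frozen=True)
class HSVRange:
    """Inclusive HSV box; H on 0-179, S and V on 0-255."""

    lower: tuple
    upper: tuple

    def __post_init__(self):
        if len(self.lower) != 3 or len(self.upper) != 3:
            raise ValueError("HSV bounds must be (H, S, V) triples")
        if any(l > u for l, u in zip(self.lower, self.upper)):
            raise ValueError("lower bound exceeds upper bound")
        if not (0 <= self.lower[0] and self.upper[0] <= 179):
            raise ValueError("H must lie in [0, 179]")
        for i in (1, 2):
            if not (0 <= self.lower[i] and self.upper[i] <= 255):
                raise ValueError("S and V must lie in [0, 255]")


# blue-to-pink fibers, plus dark near-black elastic variants
DEFAULT_FIBROUS_RANGES = (
    HSVRange((110, 50, 50), (170, 255, 255)),
    HSVRange((120, 0, 55), (150, 30, 90)),
)


@dataclass
class MetricsRecord:
    ssim: float
    psnr: float
    rmse_whole: float
    rmse_fibrous: float
    n_fibrous_pixels: int
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "ssim": self.ssim,
            "psnr": self.psnr,
            "rmse_whole": self.rmse_whole,
            "rmse_fibrous": self.rmse_fibrous,
            "n_fibrous_pixels": self.n_fibrous_pixels,
        }


def _check_pair(gt: np.ndarray, out: np.ndarray):
    gt = np.asarray(gt, dtype=float)
    out = np.asarray(out, dtype=float)
    if gt.shape != out.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {out.shape}")
    if gt.size == 0:
        raise ValueError("empty images")
    return gt, out


def mse_rmse(gt: np.ndarray, out: np.ndarray) -> tuple[float, float]:
    """Mean squared error over all H*W*C elements, and its square root."""
    gt, out = _check_pair(gt, out)
    mse = float(np.mean((gt - out) ** 2))
    return mse, float(np.sqrt(mse))


def psnr(gt: np.ndarray, out: np.ndarray, peak: float = 255.0) -> float:
    """10*log10(peak^2 / MSE) in dB; infinity sentinel for identical images."""
    mse, _ = mse_rmse(gt, out)
    if mse == 0:
        return PSNR_INF_SENTINEL
    return float(10.0 * np.log10(peak**2 / mse))


def _ssim_single_channel(a: np.ndarray, b: np.ndarray, p: SSIMParams) -> float:
    mu_a, mu_b = a.mean(), b.mean()
    # population statistics over the whole channel
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    sd_a, sd_b = np.sqrt(var_a), np.sqrt(var_b)
    lum = (2 * mu_a * mu_b + p.C1) / (mu_a**2 + mu_b**2 + p.C1)
    con = (2 * sd_a * sd_b + p.C2) / (var_a + var_b + p.C2)
    struct = (cov + p.C3) / (sd_a * sd_b + p.C3)
    return float(lum**p.alpha * con**p.beta * struct**p.gamma_exp)


def ssim_rgb(gt: np.ndarray, out: np.ndarray, params: SSIMParams | None = None) -> float:
    """Global-statistics SSIM per channel, averaged over R, G, B.

    With unit exponents this reduces to the familiar two-factor form
    ``(2 mu_a mu_b + C1)(2 cov + C2) / ((mu_a^2 + mu_b^2 + C1)(var_a + var_b + C2))``.
    """
    params = params or SSIMParams()
    gt, out = _check_pair(gt, out)
    if gt.ndim != 3 or gt.shape[2] != 3:
        raise ValueError("ssim_rgb expects H x W x 3 images")
    vals = [
        _ssim_single_channel(gt[:, :, c], out[:, :, c], params) for c in range(3)
    ]
    return float(np.mean(vals))


def ssim_windowed(gt: np.ndarray, out: np.ndarray) -> float:
    """11x11 Gaussian-windowed SSIM (scikit-image), channel-averaged.

    A conventional alternative to the global-statistics form; not used
    by the headline metrics.
    """
    from skimage.metrics import structural_similarity

    gt, out = _check_pair(gt, out)
    return float(
        structural_similarity(
            gt, out, channel_axis=2, data_range=255.0, gaussian_weights=True
        )
    )


def _rgb_to_hsv_cv(img: np.ndarray) -> np.ndarray:
    """HSV with H on 0-179 and S, V on 0-255 (integer thresholding scale)."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected H x W x 3 RGB")
    hsv = rgb2hsv(img.astype(np.uint8))
    out = np.empty_like(hsv)
    out[:, :, 0] = np.round(hsv[:, :, 0] * 179.0)
    out[:, :, 1] = np.round(hsv[:, :, 1] * 255.0)
    out[:, :, 2] = np.round(hsv[:, :, 2] * 255.0)
    return out


def fibrous_mask(evg: np.ndarray, ranges=DEFAULT_FIBROUS_RANGES) -> np.ndarray:
    """Binary mask of fibrous pixels: inside ANY of the HSV ranges."""
    hsv = _rgb_to_hsv_cv(evg)
    mask = np.zeros(hsv.shape[:2], dtype=bool)
    for r in ranges:
        if not isinstance(r, HSVRange):
            r = HSVRange(tuple(r[0]), tuple(r[1]))
        inside = np.ones(hsv.shape[:2], dtype=bool)
        for c in range(3):
            inside &= (hsv[:, :, c] >= r.lower[c]) & (hsv[:, :, c] <= r.upper[c])
        mask |= inside
    return mask


def fibrous_rmse(gt: np.ndarray, out: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    """RMSE restricted to masked pixels (all 3 channels of each)."""
    gt, out = _check_pair(gt, out)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gt.shape[:2]:
        raise ValueError("mask shape must match the image H x W")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty fibrous mask (0 pixels)")
    diff = gt[mask] - out[mask]
    return float(np.sqrt(np.mean(diff**2))), n


def evaluate_pair(
    gt: np.ndarray,
    out: np.ndarray,
    ranges=DEFAULT_FIBROUS_RANGES,
    mask_source: str = "gt",
    ssim_params: SSIMParams | None = None,
) -> MetricsRecord:
    """All metrics for one registered (ground truth, generated) pair.

    The fibrous mask is taken from the ground-truth EVG by default (it
    defines where fibers truly are); ``mask_source="union"`` also admits
    pixels that only the generated image renders as fibrous.
    """
    gt = np.asarray(gt, dtype=float)
    out_f = np.asarray(out, dtype=float)
    mse, rmse = mse_rmse(gt, out_f)
    if mask_source == "gt":
        mask = fibrous_mask(gt.astype(np.uint8), ranges)
    elif mask_source == "union":
        mask = fibrous_mask(gt.astype(np.uint8), ranges) | fibrous_mask(
            np.asarray(out).astype(np.uint8), ranges
        )
    else:
        raise ValueError("mask_source must be 'gt' or 'union'")
    if mask.any():
        rmse_fib, n_fib = fibrous_rmse(gt, out_f, mask)
    else:
        rmse_fib, n_fib = float("nan"), 0
    return MetricsRecord(
        ssim=ssim_rgb(gt, out_f, ssim_params),
        psnr=psnr(gt, out_f),
        rmse_whole=rmse,
        rmse_fibrous=rmse_fib,
        n_fibrous_pixels=n_fib,
        extras={"mse": mse},
    )


def dataset_report(records: list[MetricsRecord]) -> dict:
    """Per-image averages across a test set (finite PSNRs only)."""
    if not records:
        raise ValueError("no records to aggregate")
    finite_psnr = [r.psnr for r in records if np.isfinite(r.psnr)]
    fib = [r.rmse_fibrous for r in records if r.n_fibrous_pixels > 0]
    return {
        "n_images": len(records),
        "ssim": float(np.mean([r.ssim for r in records])),
        "psnr": float(np.mean(finite_psnr)) if finite_psnr else PSNR_INF_SENTINEL,
        "rmse_whole": float(np.mean([r.rmse_whole for r in records])),
        "rmse_fibrous": float(np.mean(fib)) if fib else float("nan"),
    }
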