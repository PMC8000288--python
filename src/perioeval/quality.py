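"""Full-reference image-quality metrics (MSE, PSNR, SSIM) and the
degrade-then-restore evaluation protocol.

The protocol mirrors the standard way upscaling methods are benchmarked when
no true low-resolution/high-resolution pairs exist: each reference image is
downscaled with a neutral area-average filter, upscaled back with the method
under test, and compared to the original. MSE/PSNR/SSIM are aggregated as
mean and sample standard deviation over the image set.

PSNR and MSE are mutually consistent per image (PSNR recomputed from a
single image's MSE reproduces that image's PSNR), but a mean PSNR over many
images is *not* the PSNR of the mean MSE — aggregate rows therefore cannot
be cross-derived from each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .resampling import resize, resize_area, quantize_u8

__all__ = ["mse", "psnr", "ssim", "IQMReport", "downup_protocol"]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    return a, b


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared intensity difference."""
    a, b = _check_shapes(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    err = mse(a, b)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(max_value**2 / err)


def _gaussian_kernel1d(size: int, sigma: float) -> np.ndarray:
    r = (size - 1) / 2.0
    x = np.arange(size) - r
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _filter2(img: np.ndarray, k1d: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(img, k1d, axis=0, mode="constant")
    return ndimage.correlate1d(out, k1d, axis=1, mode="constant")


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    window_size: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
    dynamic_range: float = 255.0,
) -> float:
    """Structural similarity index with a Gaussian-weighted sliding window.

    Local (weighted) means, variances and covariance are combined as

        ssim = (2 mu_a mu_b + C1)(2 cov + C2) /
               ((mu_a^2 + mu_b^2 + C1)(var_a + var_b + C2))

    with C1 = (k1 L)^2, C2 = (k2 L)^2 and L the dynamic range. The local
    index is averaged over positions where the window lies fully inside the
    image, so images must be at least ``window_size`` on each side.
    """
    a, b = _check_shapes(a, b)
    if min(a.shape) < window_size:
        raise ValueError("image smaller than the SSIM window")
    k1d = _gaussian_kernel1d(window_size, sigma)
    mu_a = _filter2(a, k1d)
    mu_b = _filter2(b, k1d)
    e_aa = _filter2(a * a, k1d)
    e_bb = _filter2(b * b, k1d)
    e_ab = _filter2(a * b, k1d)
    var_a = e_aa - mu_a**2
    var_b = e_bb - mu_b**2
    cov = e_ab - mu_a * mu_b
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    s = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    )
    pad = window_size // 2
    return float(s[pad:-pad, pad:-pad].mean())


@dataclass
class IQMReport:
    """Per-method aggregate metrics in the layout of a methods-comparison
    table: one row per method, mean and sample sd for each metric, ordered
    by mean MSE ascending (best first)."""

    table: pd.DataFrame
    per_image: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _sd(values: list[float]) -> float:
    # sample sd; a single image has no spread, reported as 0.0; an infinite
    # aggregate (identical images -> infinite PSNR) has no defined spread
    if len(values) < 2:
        return 0.0
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        return math.nan
    return float(np.std(arr, ddof=1))


def downup_protocol(
    images: list[np.ndarray],
    methods: list[str],
    size: int = 720,
    low: int = 128,
    srcnn_model=None,
) -> IQMReport:
    """Downscale each reference to ``low`` x ``low`` (area-average), upscale
    back to ``size`` x ``size`` with each method, and score against the
    original.

    ``methods`` entries are kernel kind names (``nearest``, ``bilinear``,
    ``bicubic``, ``lanczos``) or ``"srcnn"`` if ``srcnn_model`` is supplied.
    Restored images are quantized to 8 bits before scoring, matching the
    8-bit origin of the references.
    """
    if not images:
        raise ValueError("empty image list")
    from .resampling import srcnn_apply  # local import to avoid cycle noise

    rows = []
    for m in methods:
        for idx, img in enumerate(images):
            img = np.asarray(img, dtype=float)
            if img.shape != (size, size):
                raise ValueError(
                    f"image {idx} has shape {img.shape}, expected ({size}, {size})"
                )
            lo = resize_area(img, low, low)
            if m == "srcnn":
                if srcnn_model is None:
                    raise ValueError("method 'srcnn' requires srcnn_model")
                up = srcnn_apply(srcnn_model, lo, size / low)
            else:
                up = resize(lo, size, size, kind=m)
            up = quantize_u8(up).astype(float)
            rows.append(
                {
                    "method": m,
                    "image": idx,
                    "mse": mse(img, up),
                    "psnr": psnr(img, up),
                    "ssim": ssim(img, up),
                }
            )
    per_image = pd.DataFrame(rows)
    agg_rows = []
    for m in methods:
        sub = per_image[per_image["method"] == m]
        agg_rows.append(
            {
                "method": m,
                "mse_mean": sub["mse"].mean(),
                "mse_sd": _sd(list(sub["mse"])),
                "psnr_mean": sub["psnr"].mean(),
                "psnr_sd": _sd(list(sub["psnr"])),
                "ssim_mean": sub["ssim"].mean(),
                "ssim_sd": _sd(list(sub["ssim"])),
            }
        )
    table = (
        pd.DataFrame(agg_rows).sort_values("mse_mean").reset_index(drop=True)
    )
    return IQMReport(table=table, per_image=per_image)
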