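"""Edge-preserving denoising and background correction.

The first pipeline stage smooths the raw frame with a bilateral filter
(Gaussian spatial closeness kernel of width ``sigma_s`` and Gaussian
intensity similarity kernel of width ``sigma_c``), then removes slowly
varying background with a white top-hat (image minus its gray-scale
opening by a flat disk, radius 21 px by default). The bilateral stage
may be disabled, in which case the top-hat is applied to the raw image.

Border handling is truncation everywhere: the bilateral window is
renormalized over in-image pixels, and morphological erosion/dilation
ignore out-of-image samples (identity elements outside). A constant
image is therefore a fixed point of the bilateral filter and maps to
all zeros under the top-hat.
"""

from __future__ import annotations

import numpy as np
import scipy.fft
from scipy import ndimage

from .config import AUTO, BilateralParams, PipelineConfig, TophatParams, resolve_window_radius
from .image_io import GrayImage

__all__ = [
    "global_intensity_std",
    "bilateral_filter",
    "white_tophat",
    "preprocess_image",
    "disk_footprint",
]

# Above ~38 radiometric sigmas the Gaussian similarity weight underflows
# to exactly 0.0 in IEEE double, so intensity values further apart than
# this contribute nothing in any evaluation order.
_MAX_LEVELS_FOR_DECOMPOSITION = 4096
_DIRECT_COST_LIMIT = 2.0e8  # pixel*window operations


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, GrayImage) else np.asarray(img)


def global_intensity_std(img) -> float:
    """Population standard deviation of all pixel intensities."""
    return float(np.std(np.asarray(_pixels(img), dtype=np.float64)))


def disk_footprint(radius: int) -> np.ndarray:
    """Flat (binary) disk ``{(x, y): x^2 + y^2 <= r^2}``."""
    ax = np.arange(-radius, radius + 1)
    return (ax[:, None] ** 2 + ax[None, :] ** 2) <= radius * radius


def _resolve_bilateral(img: GrayImage, params: BilateralParams):
    sigma_c = float(params.sigma_c)
    if params.sigma_s == AUTO:
        sigma_s = global_intensity_std(img)
        if sigma_s <= 0:
            raise ValueError(
                "sigma_s='auto' on a constant image gives sigma 0; "
                "substitute a positive value"
            )
    else:
        sigma_s = float(params.sigma_s)
    if params.window_radius == AUTO:
        radius = resolve_window_radius(sigma_s, img.height, img.width)
    else:
        radius = int(params.window_radius)
    return sigma_c, sigma_s, radius


def bilateral_filter(
    img: GrayImage | np.ndarray,
    params: BilateralParams | None = None,
    *,
    method: str = "auto",
) -> GrayImage:
    """Bilateral smoothing over a square window of the given radius.

    Each output pixel is the similarity-and-closeness weighted mean of
    the in-image window around it,

    ``O(p) = sum_q I(q) c(p,q) s(p,q) / sum_q c(p,q) s(p,q)``,

    with ``c(p,q) = exp(-||p-q||^2 / (2 sigma_s^2))`` and
    ``s(p,q) = exp(-(I(p)-I(q))^2 / (2 sigma_c^2))``. Weights are
    renormalized over in-image pixels, so a constant image is a fixed
    point and the output never leaves the input intensity range.

    Two mathematically identical evaluation paths are available:
    ``"direct"`` accumulates shifted windows (any input), ``"levels"``
    decomposes the sum over the distinct intensity values of the input
    and evaluates the spatial sums by FFT convolution — much faster for
    large discrete-valued (e.g. 8-bit) frames. ``"auto"`` picks by cost.
    """
    if params is None:
        params = BilateralParams()
    gray = img if isinstance(img, GrayImage) else GrayImage(np.asarray(img), bit_depth=16)
    sigma_c, sigma_s, radius = _resolve_bilateral(gray, params)

    values = np.asarray(gray.pixels, dtype=np.float64)
    if method == "auto":
        n_levels = np.unique(values).size
        direct_cost = values.size * (2 * radius + 1) ** 2
        method = (
            "levels"
            if n_levels <= _MAX_LEVELS_FOR_DECOMPOSITION
            and direct_cost > _DIRECT_COST_LIMIT
            else "direct"
        )
    if method == "direct":
        out = _bilateral_direct(values, sigma_c, sigma_s, radius)
    elif method == "levels":
        out = _bilateral_levels(values, sigma_c, sigma_s, radius)
    else:
        raise ValueError(f"unknown bilateral method {method!r}")
    np.clip(out, values.min(), values.max(), out=out)
    return GrayImage(out, bit_depth=gray.bit_depth, source_path=gray.source_path)


def _bilateral_direct(
    I: np.ndarray, sigma_c: float, sigma_s: float, radius: int
) -> np.ndarray:
    """Windowed accumulation over all (dy, dx) offsets; exact reference path."""
    h, w = I.shape
    num = np.zeros_like(I)
    den = np.zeros_like(I)
    inv2ss = 0.5 / (sigma_s * sigma_s)
    inv2sc = 0.5 / (sigma_c * sigma_c)
    for dy in range(-radius, radius + 1):
        ys_dst = slice(max(0, -dy), h - max(0, dy))
        ys_src = slice(max(0, dy), h - max(0, -dy))
        if ys_dst.start >= h - max(0, dy):
            continue
        for dx in range(-radius, radius + 1):
            xs_dst = slice(max(0, -dx), w - max(0, dx))
            xs_src = slice(max(0, dx), w - max(0, -dx))
            c = np.exp(-(dy * dy + dx * dx) * inv2ss)
            if c == 0.0:
                continue
            src = I[ys_src, xs_src]
            dst = I[ys_dst, xs_dst]
            diff = dst - src
            wgt = c * np.exp(-(diff * diff) * inv2sc)
            num[ys_dst, xs_dst] += wgt * src
            den[ys_dst, xs_dst] += wgt
    return num / den


def _bilateral_levels(
    I: np.ndarray, sigma_c: float, sigma_s: float, radius: int
) -> np.ndarray:
    """Exact decomposition over distinct intensity values.

    Writing the weighted sums as sums over the value set V of I,

    ``den(p) = sum_{v in V} s(I(p), v) * (C * [I == v])(p)``

    (and ``num`` with an extra factor v), where C is the truncated
    spatial kernel and * a zero-padded convolution — zero padding is
    exactly the in-image renormalization, since both numerator and
    denominator lose the same out-of-image mass.
    """
    h, w = I.shape
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-0.5 * (ax / sigma_s) ** 2)
    kernel = np.outer(g, g)  # exp(-(dy^2+dx^2)/2ss^2), truncated square window

    fshape = [scipy.fft.next_fast_len(h + 2 * radius),
              scipy.fft.next_fast_len(w + 2 * radius)]
    kf = scipy.fft.rfftn(kernel, fshape)

    inv2sc = 0.5 / (sigma_c * sigma_c)
    num = np.zeros_like(I)
    den = np.zeros_like(I)
    for v in np.unique(I):
        mask = (I == v).astype(np.float64)
        conv = scipy.fft.irfftn(scipy.fft.rfftn(mask, fshape) * kf, fshape)
        conv = conv[radius:radius + h, radius:radius + w]
        diff = I - v
        wgt = np.exp(-(diff * diff) * inv2sc)
        wa = wgt * conv
        den += wa
        num += v * wa
    return num / den


def white_tophat(
    img: GrayImage | np.ndarray, params: TophatParams | None = None
) -> GrayImage:
    """White top-hat: image minus its gray-scale opening by a flat disk.

    Isolates bright structures smaller than the structuring element and
    flattens slowly varying (uneven-illumination) background. Output is
    elementwise >= 0 and <= input.
    """
    if params is None:
        params = TophatParams()
    gray = img if isinstance(img, GrayImage) else GrayImage(np.asarray(img), bit_depth=16)
    values = np.asarray(gray.pixels, dtype=np.float64)
    h, w = values.shape
    if params.radius > max(h, w):
        raise ValueError(
            f"top-hat radius {params.radius} exceeds both image dimensions"
        )
    fp = disk_footprint(params.radius)
    # Truncation convention: out-of-image samples are the identity of
    # each stage (+inf for erosion, -inf for dilation).
    eroded = ndimage.grey_erosion(values, footprint=fp, mode="constant", cval=np.inf)
    opened = ndimage.grey_dilation(eroded, footprint=fp, mode="constant", cval=-np.inf)
    return GrayImage(values - opened, bit_depth=gray.bit_depth,
                     source_path=gray.source_path)


def preprocess_image(img: GrayImage, cfg: PipelineConfig | None = None) -> GrayImage:
    """Bilateral smoothing (unless disabled) followed by white top-hat.

    A constant frame is a bilateral fixed point for any bandwidth, so
    when the automatic sigma_s (the global intensity std) degenerates
    to 0 the smoothing stage passes the image through unchanged.
    """
    if cfg is None:
        cfg = PipelineConfig()
    smoothed = img
    if cfg.bilateral.enabled:
        degenerate = (
            cfg.bilateral.sigma_s == AUTO and global_intensity_std(img) == 0.0
        )
        if not degenerate:
            smoothed = bilateral_filter(img, cfg.bilateral)
    return white_tophat(smoothed, cfg.tophat)
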