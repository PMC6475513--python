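"""Image pre-processing: intensity adjustment, illumination correction, denoising.

The pre-processing stage compensates for the three acquisition defects that
dominate fluorescence whole-mount imaging: poor contrast, uneven illumination
(vignetting) and sensor noise.  The fixed operator order is

    adjust -> illumination-correct (white top-hat) -> denoise

with every step individually switchable.

Histogram conventions: every histogram-based operator works on 256 uniform
bins over ``[0, 1]`` with ``bin = floor(value * 255)`` (value 1.0 in the top
bin), matching the 8-bit framing of typical micrograph datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import GrayImage

logger = logging.getLogger(__name__)

NBINS = 256


class ParameterError(ValueError):
    """Invalid pre-processing parameter."""


@dataclass
class PreprocessParams:
    """Tunable parameters of the pre-processing stage.

    adjust_method: ``auto_contrast`` | ``hist_eq`` | ``clahe`` | ``none``.
    saturation_quantile: fraction of pixels saturated at each intensity end
        by auto-contrast (default 0.01, i.e. 1%).
    tophat_radius: radius in pixels of the disk structuring element of the
        white top-hat (default 51); 0 disables illumination correction.
    denoiser: ``bm3d`` | ``wiener`` | ``none``.
    """

    adjust_method: str = "auto_contrast"
    saturation_quantile: float = 0.01
    clahe_tile: int = 64
    clahe_clip: float = 0.01
    tophat_radius: int = 51
    denoiser: str = "bm3d"
    wiener_window: int = 5
    bm3d_sigma: float | str = "auto"

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturation_quantile < 0.5:
            raise ParameterError("saturation_quantile must be in [0, 0.5)")
        if self.tophat_radius < 0:
            raise ParameterError("tophat_radius must be >= 0")
        if self.wiener_window < 3 or self.wiener_window % 2 == 0:
            raise ParameterError("wiener_window must be odd and >= 3")
        if self.adjust_method not in ("auto_contrast", "hist_eq", "clahe", "none"):
            raise ParameterError(f"unknown adjust_method {self.adjust_method!r}")
        if self.denoiser not in ("bm3d", "wiener", "none"):
            raise ParameterError(f"unknown denoiser {self.denoiser!r}")


def bin_index(pixels: np.ndarray) -> np.ndarray:
    """256-bin index of each intensity: ``floor(v * 255)`` clipped to [0, 255]."""
    return np.clip(np.floor(np.asarray(pixels) * (NBINS - 1)), 0, NBINS - 1).astype(
        np.int64
    )


def disk_footprint(radius: int) -> np.ndarray:
    """Discrete disk: pixel (r, c) belongs iff r**2 + c**2 <= radius**2."""
    if radius < 1:
        raise ParameterError("disk radius must be >= 1")
    a = np.arange(-radius, radius + 1)
    rr, cc = np.meshgrid(a, a, indexing="ij")
    return (rr * rr + cc * cc) <= radius * radius


def adjust_autocontrast(img: GrayImage, q: float = 0.01) -> GrayImage:
    """Linear contrast stretch with ``q``-quantile saturation at both ends.

    Pixels at or below the ``q`` quantile map to 0, at or above the
    ``1 - q`` quantile map to 1, intermediate values are linearly
    interpolated.  A (near-)constant image is returned unchanged.
    """
    if not 0.0 <= q < 0.5:
        raise ParameterError("saturation quantile must be in [0, 0.5)")
    px = img.pixels
    p_low, p_high = np.quantile(px, [q, 1.0 - q])
    if p_high <= p_low:
        logger.warning("auto-contrast: degenerate intensity range, image unchanged")
        return img
    return img.with_pixels((px - p_low) / (p_high - p_low))


def _clipped_cdf_map(counts: np.ndarray, clip_count: float) -> np.ndarray:
    """Histogram -> monotone [0,1] mapping per bin, with optional clipping.

    Counts above ``clip_count`` are clipped and the excess redistributed
    uniformly over all bins before the CDF is formed.
    """
    counts = counts.astype(float)
    if np.isfinite(clip_count):
        excess = np.maximum(counts - clip_count, 0.0).sum()
        counts = np.minimum(counts, clip_count) + excess / NBINS
    total = counts.sum()
    if total == 0:
        return np.linspace(0, 1, NBINS)
    return np.cumsum(counts) / total


def equalize_histogram(img: GrayImage) -> GrayImage:
    """Global histogram equalisation via the empirical CDF on 256 bins.

    Each pixel maps to ``CDF(bin(pixel))`` so the output histogram is
    approximately uniform; the mapping is monotone non-decreasing and the
    top occupied bin maps to exactly 1.
    """
    b = bin_index(img.pixels)
    counts = np.bincount(b.ravel(), minlength=NBINS)
    cdf = _clipped_cdf_map(counts, np.inf)
    return img.with_pixels(cdf[b])


def clahe(img: GrayImage, tile: int, clip: float = 0.01) -> GrayImage:
    """Contrast-limited adaptive histogram equalisation.

    The image is divided into ``tile x tile`` patches; each patch gets a
    clipped-CDF mapping (clip limit = ``clip`` as a fraction of the patch
    pixel count; ``inf`` disables clipping) and per-pixel output is the
    bilinear interpolation between the mappings of the four surrounding
    patch centres.  With one patch covering the whole image and no clipping
    this reduces exactly to :func:`equalize_histogram`.
    """
    H, W = img.pixels.shape
    if tile > min(H, W):
        raise ParameterError(f"clahe tile {tile} larger than image {img.pixels.shape}")
    if tile < 2:
        raise ParameterError("clahe tile must be >= 2")
    b = bin_index(img.pixels)
    # tile grid; last tile absorbs the remainder
    ny, nx = max(H // tile, 1), max(W // tile, 1)
    ybounds = [round(i * H / ny) for i in range(ny + 1)]
    xbounds = [round(j * W / nx) for j in range(nx + 1)]
    maps = np.empty((ny, nx, NBINS))
    ycent = np.empty(ny)
    xcent = np.empty(nx)
    for i in range(ny):
        for j in range(nx):
            sub = b[ybounds[i]:ybounds[i + 1], xbounds[j]:xbounds[j + 1]]
            counts = np.bincount(sub.ravel(), minlength=NBINS)
            clip_count = clip * sub.size if np.isfinite(clip) else np.inf
            maps[i, j] = _clipped_cdf_map(counts, clip_count)
            ycent[i] = (ybounds[i] + ybounds[i + 1] - 1) / 2.0
            xcent[j] = (xbounds[j] + xbounds[j + 1] - 1) / 2.0
    # bilinear interpolation between tile-centre mappings (clamped outside)
    yy = np.arange(H, dtype=float)
    xx = np.arange(W, dtype=float)
    yi = np.clip(np.searchsorted(ycent, yy) - 1, 0, max(ny - 2, 0))
    xi = np.clip(np.searchsorted(xcent, xx) - 1, 0, max(nx - 2, 0))
    if ny > 1:
        wy = np.clip((yy - ycent[yi]) / (ycent[yi + 1] - ycent[yi]), 0.0, 1.0)
    else:
        wy = np.zeros(H)
    if nx > 1:
        wx = np.clip((xx - xcent[xi]) / (xcent[xi + 1] - xcent[xi]), 0.0, 1.0)
    else:
        wx = np.zeros(W)
    yi0 = yi[:, None]
    yi1 = np.minimum(yi + 1, ny - 1)[:, None]
    xi0 = xi[None, :]
    xi1 = np.minimum(xi + 1, nx - 1)[None, :]
    wy2 = wy[:, None]
    wx2 = wx[None, :]
    v00 = maps[yi0, xi0, b]
    v01 = maps[yi0, xi1, b]
    v10 = maps[yi1, xi0, b]
    v11 = maps[yi1, xi1, b]
    out = ((1 - wy2) * (1 - wx2) * v00 + (1 - wy2) * wx2 * v01
           + wy2 * (1 - wx2) * v10 + wy2 * wx2 * v11)
    return img.with_pixels(out)


def tophat_correct(img: GrayImage, radius: int = 51) -> GrayImage:
    """White top-hat illumination correction.

    ``output = img - opening(img, disk(radius))``: structures wider than the
    disk in both dimensions (the smooth background, including vignetting
    gradients) are suppressed while narrower structures (vessels) keep their
    local contrast.
    """
    fp = disk_footprint(radius)
    opened = ndimage.grey_opening(img.pixels, footprint=fp, mode="reflect")
    return img.with_pixels(img.pixels - opened)


def denoise_wiener(img: GrayImage, window: int = 5) -> GrayImage:
    """Locally adaptive (Wiener) filter.

    Per-window mean and variance drive the classic pixel-wise estimate

        out = m + max(v - n, 0) / v * (img - m)

    with the noise power ``n`` estimated globally as the mean of the local
    variances.  Borders are handled by reflective padding; a constant image
    is returned unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError("wiener window must be odd and >= 3")
    px = img.pixels
    mean = ndimage.uniform_filter(px, size=window, mode="reflect")
    meansq = ndimage.uniform_filter(px * px, size=window, mode="reflect")
    var = np.maximum(meansq - mean * mean, 0.0)
    noise = var.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(var > 0, np.maximum(var - noise, 0.0) / var, 0.0)
    return img.with_pixels(mean + gain * (px - mean))


def preprocess(img: GrayImage, params: PreprocessParams) -> GrayImage:
    """Run the full pre-processing chain on one image."""
    from .bm3d import denoise_bm3d  # local import: bm3d is heavy

    out = img
    if params.adjust_method == "auto_contrast":
        out = adjust_autocontrast(out, params.saturation_quantile)
    elif params.adjust_method == "hist_eq":
        out = equalize_histogram(out)
    elif params.adjust_method == "clahe":
        out = clahe(out, params.clahe_tile, params.clahe_clip)
    if params.tophat_radius >= 1:
        out = tophat_correct(out, params.tophat_radius)
    if params.denoiser == "wiener":
        out = denoise_wiener(out, params.wiener_window)
    elif params.denoiser == "bm3d":
        out = denoise_bm3d(out, params.bm3d_sigma)
    return out
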