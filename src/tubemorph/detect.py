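"""Tube detection: vesselness enhancement, thresholding, mask refinement.

Detection turns the pre-processed grey image into a binary vessel mask.
Bright-on-dark polarity is fixed: vessels are assumed brighter than the
background.  Optionally the image is first enhanced with the Frangi
vesselness filter ("detect finer tubes"), which scores bright elongated
structures through the eigenvalues of the Gaussian-scale Hessian — useful
when staining is weak.  The enhanced (or raw pre-processed) image is then
binarised with one of four thresholding methods:

* Otsu — minimises within-class intensity variance of a two-class split;
* Multi-Otsu — same criterion generalised to ``n`` classes, foreground being
  the brightest class(es);
* Kittler–Illingworth minimum error — fits two Gaussians to the histogram
  and minimises the classification-error criterion; tends to pick lower
  thresholds and thus captures weakly stained vessels;
* Adaptive — per-pixel comparison against the local mean.

All histogram methods operate on the shared 256-bin framing of [0, 1]
(``bin = floor(v * 255)``); a threshold is reported as a bin index ``t``
with foreground = pixels whose bin exceeds ``t``.

Refinement removes small 8-connected components (below a fraction of the
image pixel count, default 1%) and optionally fills enclosed background
holes (4-connected, not touching the border).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import frangi as _skimage_frangi

from .image_io import GrayImage
from .preprocess import NBINS, ParameterError, bin_index

#: 8-connectivity structure for foreground labelling
STRUCT8 = np.ones((3, 3), bool)


class DegenerateHistogramError(ValueError):
    """Histogram has too few distinct occupied bins to threshold."""


@dataclass
class DetectParams:
    """Parameters of the detection stage (thresholding + refinement)."""

    use_vesselness: bool = False
    frangi_scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    frangi_beta: float = 0.5
    frangi_c: float | None = None  # None -> half the max Hessian norm per image
    threshold_method: str = "multi_otsu"
    multiotsu_classes: int = 3
    multiotsu_foreground_classes: int = 1
    adaptive_block: int = 31
    adaptive_offset: float = 0.02
    min_region_fraction: float = 0.01
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.frangi_scales):
            raise ParameterError("frangi scales must be positive")
        if not 2 <= self.multiotsu_classes <= 5:
            raise ParameterError("multiotsu_classes must be in [2, 5]")
        if not 1 <= self.multiotsu_foreground_classes < self.multiotsu_classes:
            raise ParameterError("foreground classes must be in [1, n_classes)")
        if not 0.0 <= self.min_region_fraction < 1.0:
            raise ParameterError("min_region_fraction must be in [0, 1)")
        if self.threshold_method not in ("otsu", "multi_otsu", "kittler", "adaptive"):
            raise ParameterError(f"unknown threshold method {self.threshold_method!r}")


@dataclass(frozen=True)
class IntensityHistogram:
    """256-bin intensity histogram over [0, 1]."""

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (NBINS,) or c.sum() != self.total:
            raise ValueError("histogram counts must be 256 bins summing to total")
        object.__setattr__(self, "counts", c)


def compute_histogram(img: GrayImage | np.ndarray) -> IntensityHistogram:
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    b = bin_index(px)
    counts = np.bincount(b.ravel(), minlength=NBINS)
    return IntensityHistogram(counts, int(counts.sum()))


def frangi_vesselness(
    img: GrayImage,
    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0),
    beta: float = 0.5,
    c: float | None = None,
) -> GrayImage:
    """Frangi vesselness response for bright tubes, rescaled to [0, 1].

    Per scale sigma the Hessian eigenvalues ``|l1| <= |l2|`` give blobness
    ``R_b = l1/l2`` and structure strength ``S = sqrt(l1^2 + l2^2)``; the
    response is ``exp(-R_b^2/2 beta^2) * (1 - exp(-S^2/2 c^2))`` wherever
    ``l2 < 0`` (bright ridge) and 0 elsewhere, maximised over scales.
    ``c=None`` uses half the maximum Hessian norm of the image.
    """
    if len(scales) == 0:
        raise ParameterError("need at least one vesselness scale")
    if any(s <= 0 for s in scales):
        raise ParameterError("vesselness scales must be positive")
    resp = _skimage_frangi(
        img.pixels, sigmas=scales, beta=beta, gamma=c, black_ridges=False
    )
    top = resp.max()
    if top > 0:
        resp = resp / top
    return img.with_pixels(resp)


def _class_stats(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative (mass, first moment, second moment) over bin index."""
    idx = np.arange(NBINS, dtype=float)
    c = counts.astype(float)
    return np.cumsum(c), np.cumsum(c * idx), np.cumsum(c * idx * idx)


def threshold_otsu(hist: IntensityHistogram) -> int:
    """Otsu threshold: bin index t maximising between-class variance.

    Foreground is ``bin > t``.  Ties break to the lowest t.
    """
    counts = hist.counts
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("need >= 2 occupied bins for Otsu")
    w, m, _ = _class_stats(counts)
    w0 = w[:-1]
    w1 = w[-1] - w0
    mu_t = m[-1]
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        # between-class variance up to the constant total mass
        crit = (mu_t * w0 - m[:-1] * w[-1]) ** 2 / (w0 * w1)
    crit[~valid] = -np.inf
    return int(np.argmax(crit))


def threshold_multiotsu(hist: IntensityHistogram, n_classes: int = 3) -> list[int]:
    """Multi-Otsu thresholds: ``n_classes - 1`` ordered bin indices.

    The thresholds maximise the between-class variance
    ``sum_k w_k mu_k^2`` over all ways of splitting the 256 bins into
    ``n_classes`` contiguous classes (class k = bins in (t_{k-1}, t_k]).
    Found by exhaustive search; ties break to the lexicographically
    smallest tuple.  With ``n_classes=2`` this is exactly Otsu.
    """
    if not 2 <= n_classes <= 5:
        raise ParameterError("n_classes must be in [2, 5]")
    counts = hist.counts
    if np.count_nonzero(counts) < n_classes:
        raise DegenerateHistogramError(
            f"need >= {n_classes} occupied bins for {n_classes}-class Multi-Otsu"
        )
    w, m, _ = _class_stats(counts)
    w = np.concatenate([[0.0], w])  # w[i] = mass of bins < i
    m = np.concatenate([[0.0], m])

    def seg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """w * mu^2 of the class spanning bins [a, b) (0 where empty)."""
        mass = w[b] - w[a]
        mom = m[b] - m[a]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(mass > 0, mom * mom / np.maximum(mass, 1e-300), 0.0)

    cuts = np.arange(1, NBINS)  # cut c: bins < c | bins >= c
    if n_classes == 2:
        crit = seg(np.zeros_like(cuts), cuts) + seg(cuts, np.full_like(cuts, NBINS))
        best = [int(np.argmax(crit)) + 1]
    else:
        best_val = -np.inf
        best = []
        # loop the first cut, broadcast the remaining ones
        for c1 in range(1, NBINS - (n_classes - 2)):
            first = seg(np.array([0]), np.array([c1]))[0]
            rest_cuts = np.arange(c1 + 1, NBINS)
            if n_classes == 3:
                crit = first + seg(np.full_like(rest_cuts, c1), rest_cuts) + seg(
                    rest_cuts, np.full_like(rest_cuts, NBINS)
                )
                k = int(np.argmax(crit))
                if crit[k] > best_val:
                    best_val = crit[k]
                    best = [c1, int(rest_cuts[k])]
            else:
                sub = threshold_multiotsu_tail(w, m, seg, c1, n_classes - 1)
                if sub is None:
                    continue
                val, cuts_rest = sub
                if first + val > best_val:
                    best_val = first + val
                    best = [c1, *cuts_rest]
    # report thresholds as "foreground above" bin indices: t = cut - 1
    return [c - 1 for c in best]


def threshold_multiotsu_tail(w, m, seg, start: int, k: int):
    """Best k-class split of bins [start, 256); recursive helper for n>=4."""
    if k == 2:
        cuts = np.arange(start + 1, NBINS)
        if cuts.size == 0:
            return None
        crit = seg(np.full_like(cuts, start), cuts) + seg(
            cuts, np.full_like(cuts, NBINS)
        )
        i = int(np.argmax(crit))
        return float(crit[i]), [int(cuts[i])]
    best = None
    for c in range(start + 1, NBINS - (k - 2)):
        first = seg(np.array([start]), np.array([c]))[0]
        sub = threshold_multiotsu_tail(w, m, seg, c, k - 1)
        if sub is None:
            continue
        val, cuts_rest = sub
        if best is None or first + val > best[0]:
            best = (first + val, [c, *cuts_rest])
    return best


def threshold_kittler(hist: IntensityHistogram) -> int:
    """Kittler–Illingworth minimum-error threshold (bin index).

    Minimises ``J(t) = 1 + 2[P1 ln s1 + P2 ln s2] - 2[P1 ln P1 + P2 ln P2]``
    where ``P``, ``s`` are the prior and standard deviation of the two
    classes split at t (class 1 = bins <= t).  Class variances are floored
    at one bin width squared; candidates leaving either class empty are
    skipped; ties break to the lowest t.
    """
    counts = hist.counts
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("need >= 2 occupied bins for Kittler")
    w, m, m2 = _class_stats(counts)
    total = w[-1]
    w0 = w[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (m[-1] - m[:-1]) / w1
        var0 = m2[:-1] / w0 - mu0**2
        var1 = (m2[-1] - m2[:-1]) / w1 - mu1**2
        var0 = np.maximum(var0, 1.0)  # floor: one bin width squared
        var1 = np.maximum(var1, 1.0)
        p0 = w0 / total
        p1 = w1 / total
        crit = 1.0 + p0 * np.log(var0) + p1 * np.log(var1) - 2.0 * (
            p0 * np.log(p0) + p1 * np.log(p1)
        )
    crit[~valid] = np.inf
    if not np.isfinite(crit).any():
        raise DegenerateHistogramError("no valid Kittler candidate threshold")
    return int(np.argmin(crit))


def threshold_adaptive(
    img: GrayImage, block: int = 31, offset: float = 0.02
) -> np.ndarray:
    """Local-mean adaptive threshold.

    Foreground iff ``intensity > local_mean(block) + offset``; a positive
    offset therefore demands local contrast (a constant image yields an
    empty mask).  The local mean uses reflective padding at the borders.
    """
    if block % 2 == 0 or block < 3:
        raise ParameterError("adaptive block must be odd and >= 3")
    if block > min(img.pixels.shape):
        raise ParameterError("adaptive block larger than image")
    local_mean = ndimage.uniform_filter(img.pixels, size=block, mode="reflect")
    return img.pixels > local_mean + offset


def apply_threshold(img: GrayImage | np.ndarray, t: int) -> np.ndarray:
    """Binary mask from a histogram threshold: foreground = bin(pixel) > t."""
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    return bin_index(px) > t


def binarize(img: GrayImage, params: DetectParams) -> tuple[np.ndarray, float]:
    """Binarise the (pre-processed) image; returns ``(mask, threshold_used)``.

    With ``use_vesselness`` the Frangi response replaces the image before
    thresholding.  ``threshold_used`` is the bin index for histogram methods
    and NaN for the adaptive method.
    """
    work = img
    if params.use_vesselness:
        work = frangi_vesselness(
            img, params.frangi_scales, params.frangi_beta, params.frangi_c
        )
    if params.threshold_method == "adaptive":
        return (
            threshold_adaptive(work, params.adaptive_block, params.adaptive_offset),
            float("nan"),
        )
    hist = compute_histogram(work)
    if params.threshold_method == "otsu":
        t = threshold_otsu(hist)
    elif params.threshold_method == "kittler":
        t = threshold_kittler(hist)
    else:
        ts = threshold_multiotsu(hist, params.multiotsu_classes)
        t = ts[-params.multiotsu_foreground_classes]
    return apply_threshold(work, t), float(t)


def remove_small_regions(mask: np.ndarray, min_fraction: float) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_fraction`` of the image.

    A component with pixel count strictly below ``min_fraction * H * W`` is
    removed; a component exactly at the cutoff is kept.
    """
    if not 0.0 <= min_fraction < 1.0:
        raise ParameterError("min_fraction must be in [0, 1)")
    if min_fraction == 0.0:
        return mask.copy()
    labels, n = ndimage.label(mask, structure=STRUCT8)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    cutoff = min_fraction * mask.size
    keep = sizes >= cutoff
    keep[0] = False
    return keep[labels]


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill 4-connected background regions that do not touch the border."""
    return ndimage.binary_fill_holes(mask)


def refine_mask(mask: np.ndarray, params: DetectParams) -> np.ndarray:
    """Small-region removal followed by optional hole filling."""
    out = remove_small_regions(mask, params.min_region_fraction)
    if params.fill_holes:
        out = fill_holes(out)
    return out
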