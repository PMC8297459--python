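"""Foreground extraction and nucleus seed selection.

From the pre-processed (background-corrected) image this module builds
the refined foreground mask and one labeled marker per putative
nucleus, in the published order:

1. Otsu global thresholding;
2. hole filling;
3. morphological opening (disk radius 1) to sever loose connections;
4. removal of components smaller than 40 px (strict);
5. morphological closing (disk radius 2) to smooth boundaries;
6. approximate Euclidean distance transform (5x5 chamfer mask);
7. linear stretch of the distance map to the 8-bit range;
8. regional maxima (5x5 window) dilated by a disk of radius 3 and
   connected-component labeled into seeds — the dilation merges
   near-coincident maxima of one nucleus into a single seed.

Connectivity conventions (fixed once): 8-connectivity for foreground
components and plateaus, 4-connectivity for the background in hole
filling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology as skmorph

from ._chamfer import CHAMFER_ERROR_BOUND, chamfer_distance
from .config import SeedParams
from .image_io import BinaryMask, GrayImage
from .preprocess import disk_footprint

__all__ = [
    "DistanceMap",
    "SeedSet",
    "DegenerateImageError",
    "otsu_threshold",
    "fill_holes",
    "morph_open",
    "morph_close",
    "remove_small_objects",
    "refine_mask",
    "distance_transform",
    "normalize_distance",
    "regional_maxima",
    "build_seeds",
    "seeds_from_maxima",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


class DegenerateImageError(ValueError):
    """Input admits no meaningful result (e.g. constant image)."""


@dataclass
class DistanceMap:
    """Distance-to-background raster; 0 exactly on background pixels."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("DistanceMap requires a 2-D array")


@dataclass
class SeedSet:
    """Labeled marker raster; labels 1..K, one connected marker each."""

    markers: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=np.int64)
        if self.markers.ndim != 2:
            raise ValueError("SeedSet requires a 2-D marker raster")


def _mask_array(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.pixels
    return np.asarray(mask, dtype=bool)


def _image_array(img) -> np.ndarray:
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    return np.asarray(arr, dtype=np.float64)


def otsu_threshold(img, n_bins: int = 256) -> BinaryMask:
    """Global threshold maximizing between-class variance; mask = pixels > t*.

    The histogram contract is fixed so the result is well defined on
    float data: ``n_bins`` equal-width bins spanning [min, max], the
    threshold is the center of the last bin of the background class,
    ties resolved toward the lowest threshold.
    """
    arr = _image_array(img)
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        raise DegenerateImageError("constant image has no Otsu threshold")
    hist, edges = np.histogram(arr, bins=n_bins, range=(lo, hi))
    hist = hist.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    mu = np.cumsum(hist * centers)
    # between-class variance for a split after bin k (class 0 = bins <= k)
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    mu0 = np.where(w0[:-1] > 0, mu[:-1] / np.maximum(w0[:-1], 1), 0.0)
    mu1 = np.where(w1[:-1] > 0, (mu[-1] - mu[:-1]) / np.maximum(w1[:-1], 1), 0.0)
    sigma_b = np.where(valid, w0[:-1] * w1[:-1] * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    threshold = centers[k]
    return BinaryMask(arr > threshold)


def fill_holes(mask) -> BinaryMask:
    """Fill background components not 4-connected to the image border."""
    return BinaryMask(ndimage.binary_fill_holes(_mask_array(mask), structure=_STRUCT4))


def morph_open(mask, radius: int) -> BinaryMask:
    """Binary opening by a flat disk; out-of-image samples are ignored."""
    fp = disk_footprint(radius)
    m = _mask_array(mask)
    eroded = ndimage.binary_erosion(m, structure=fp, border_value=1)
    return BinaryMask(ndimage.binary_dilation(eroded, structure=fp, border_value=0))


def morph_close(mask, radius: int) -> BinaryMask:
    """Binary closing by a flat disk; out-of-image samples are ignored."""
    fp = disk_footprint(radius)
    m = _mask_array(mask)
    dilated = ndimage.binary_dilation(m, structure=fp, border_value=0)
    return BinaryMask(ndimage.binary_erosion(dilated, structure=fp, border_value=1))


def remove_small_objects(mask, min_area: int) -> BinaryMask:
    """Delete 8-connected components with strictly fewer than min_area pixels."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    m = _mask_array(mask)
    # strict "< min_area": components of exactly min_area pixels survive
    return BinaryMask(
        skmorph.remove_small_objects(m, max_size=min_area - 1, connectivity=2)
    )


def refine_mask(mask, params: SeedParams | None = None) -> BinaryMask:
    """Foreground refinement steps 2-5, in the contract's fixed order."""
    if params is None:
        params = SeedParams()
    out = fill_holes(mask)
    out = morph_open(out, params.open_radius)
    out = remove_small_objects(out, params.min_area)
    return morph_close(out, params.close_radius)


def distance_transform(
    mask, edt_mask: int = 5, *, border_is_background: bool = False
) -> DistanceMap:
    """Approximate Euclidean distance to the nearest background pixel.

    Two-pass chamfer propagation with the 3x3 or 5x5 neighborhood (see
    :mod:`nucseg._chamfer` for the weights and error bounds). By
    default the frame edge is not a distance source; an all-foreground
    mask is then degenerate. With ``border_is_background`` a virtual
    background ring outside the frame bounds the distances instead.

    Values are rounded to 9 decimals so that geometrically symmetric
    pixels, whose minimal chamfer paths accumulate the same weights in
    different orders, compare exactly equal in the plateau analysis.
    """
    m = _mask_array(mask)
    if border_is_background:
        padded = np.pad(m, 2, mode="constant", constant_values=False)
        dist = chamfer_distance(padded, edt_mask)[2:-2, 2:-2]
    else:
        if m.all() and m.size > 0:
            raise DegenerateImageError(
                "all-foreground mask has unbounded distances; "
                "set border_is_background to bound them by the frame edge"
            )
        dist = chamfer_distance(m, edt_mask)
    return DistanceMap(np.round(dist, 9))


def normalize_distance(dmap: DistanceMap) -> DistanceMap:
    """Linear contrast stretch of the distance map to [0, 255].

    Convention for a constant-nonzero map (no background present):
    foreground maps to 255, background to 0.
    """
    if dmap.normalized:
        raise ValueError("distance map is already normalized")
    vals = dmap.values
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        out = np.where(vals > 0, 255.0, 0.0)
    else:
        out = (vals - lo) * (255.0 / (hi - lo))
    return DistanceMap(out, normalized=True)


def regional_maxima(dmap: DistanceMap, window: int = 5) -> BinaryMask:
    """Plateaus strictly above their external boundary, under a square window.

    A regional maximum is a connected component of constant value whose
    external boundary pixels (within the ``window`` x ``window`` square
    neighborhood) all have a strictly lower value. Background (value 0)
    is never marked.
    """
    if not dmap.normalized:
        raise ValueError("regional maxima are computed on the normalized map")
    fp = np.ones((window, window), dtype=bool)
    values = dmap.values
    neigh_max = ndimage.maximum_filter(values, footprint=fp,
                                       mode="constant", cval=-np.inf)
    # A pixel with a strictly higher window-neighbor is disqualified;
    # disqualification then spreads across its equal-value plateau
    # (window adjacency) until the whole plateau is rejected. Pixels
    # never reached belong to plateaus strictly above their boundary.
    bad = neigh_max > values
    while True:
        bad_vals = np.where(bad, values, -np.inf)
        bad_neigh = ndimage.maximum_filter(bad_vals, footprint=fp,
                                           mode="constant", cval=-np.inf)
        # for a not-yet-bad pixel every neighbor is <= its value, so a
        # bad-neighbor maximum equal to the value means an equal-valued
        # bad plateau mate
        newly = ~bad & (bad_neigh == values)
        if not newly.any():
            break
        bad |= newly
    return BinaryMask(~bad & (values > 0))


def seeds_from_maxima(maxima, dilate_radius: int) -> SeedSet:
    """Dilate maxima by a flat disk and label 8-connected components.

    Maxima whose dilations touch merge into a single seed — this is
    what fuses the few near-coincident peaks a single nucleus can
    produce into one marker.
    """
    fp = disk_footprint(dilate_radius)
    dilated = ndimage.binary_dilation(_mask_array(maxima), structure=fp,
                                      border_value=0)
    markers, k = ndimage.label(dilated, structure=_STRUCT8)
    return SeedSet(markers, int(k))


def build_seeds(mask_refined, dmap: DistanceMap, params: SeedParams | None = None) -> SeedSet:
    """Regional maxima of the normalized distance map, dilated and labeled."""
    if params is None:
        params = SeedParams()
    maxima = regional_maxima(dmap, params.maxima_window)
    return seeds_from_maxima(maxima, params.dilate_radius)


#: Re-exported documented error bounds of the chamfer approximation.
DISTANCE_ERROR_BOUND = CHAMFER_ERROR_BOUND
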