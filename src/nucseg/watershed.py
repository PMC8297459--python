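"""Marker-controlled watershed segmentation and the full pipeline.

The edge landscape is the discrete Laplacian of the pre-processed
image; flooding starts from the seed markers and proceeds through a
priority queue keyed on (edge value, insertion order): pixels are
dequeued in increasing edge value, ties broken first-in-first-out, so
plateaus are scanned breadth-first and each contested pixel goes to
the marker whose front reached it first. Every flooded pixel receives
the label of the neighbor that enqueued it; markers are never
relabeled.

Flooding uses 4-connectivity (pairing with the 8-connected foreground
convention) and is confined to the refined foreground mask, so basins
never leak into background.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .image_io import GrayImage, LabelMap
from .preprocess import preprocess_image
from .seeds import (
    DegenerateImageError,
    SeedSet,
    distance_transform,
    normalize_distance,
    otsu_threshold,
    refine_mask,
    regional_maxima,
    seeds_from_maxima,
)

__all__ = [
    "laplacian_edges",
    "marker_watershed",
    "segment_image",
    "segment_stages",
    "instances_from_preprocessed",
    "count_cells",
    "draw_boundary_lines",
]

_LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)
_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def laplacian_edges(img) -> np.ndarray:
    """Discrete Laplacian (4-neighbor stencil), reflective borders."""
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    arr = np.asarray(arr, dtype=np.float64)
    return ndimage.convolve(arr, _LAPLACIAN_KERNEL, mode="reflect")


def marker_watershed(
    edges: np.ndarray,
    seeds: SeedSet,
    mask: np.ndarray | None = None,
) -> LabelMap:
    """Flood the edge landscape from the markers.

    Parameters
    ----------
    edges
        Real-valued landscape (higher = more ridge-like).
    seeds
        Labeled markers; label pixels keep their label in the output.
    mask
        Optional flooding domain. Marker pixels are always part of the
        domain; pixels outside it stay background.
    """
    E = np.asarray(edges, dtype=np.float64)
    markers = seeds.markers
    if E.shape != markers.shape:
        raise ValueError(f"shape mismatch: edges {E.shape} vs markers {markers.shape}")
    h, w = E.shape
    out = markers.copy()
    if mask is None:
        domain = np.ones_like(out, dtype=bool)
    else:
        domain = np.asarray(mask, dtype=bool) | (markers > 0)

    heap: list[tuple[float, int, int, int, int]] = []
    order = 0
    # Seed the queue with the unlabeled in-domain 4-neighbors of the
    # marker pixels, visited in raster order: the FIFO tie-break then
    # depends only on pixel geometry, not on marker label values.
    for i, j in zip(*np.nonzero(markers)):
        lab = int(markers[i, j])
        for di, dj in _N4:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and domain[ni, nj] and out[ni, nj] == 0:
                heapq.heappush(heap, (E[ni, nj], order, ni, nj, lab))
                order += 1
    while heap:
        _, _, i, j, lab = heapq.heappop(heap)
        if out[i, j] != 0:
            continue
        out[i, j] = lab
        for di, dj in _N4:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and domain[ni, nj] and out[ni, nj] == 0:
                heapq.heappush(heap, (E[ni, nj], order, ni, nj, lab))
                order += 1
    return LabelMap(out)


def draw_boundary_lines(label_map: LabelMap) -> LabelMap:
    """Zero-valued 1-px dams between 4-adjacent distinct instances.

    For each adjacent pair the pixel carrying the larger label is
    cleared, giving a single-pixel separating line for visualization;
    counting and overlap metrics use the dam-free map.
    """
    lab = label_map.labels
    out = lab.copy()
    for axis, shift in ((0, 1), (1, 1)):
        a = lab[:-1, :] if axis == 0 else lab[:, :-1]
        b = lab[1:, :] if axis == 0 else lab[:, 1:]
        touching = (a > 0) & (b > 0) & (a != b)
        if axis == 0:
            out[:-1, :][touching & (a > b)] = 0
            out[1:, :][touching & (b > a)] = 0
        else:
            out[:, :-1][touching & (a > b)] = 0
            out[:, 1:][touching & (b > a)] = 0
    return LabelMap(out)


def instances_from_preprocessed(
    pre: GrayImage,
    cfg: PipelineConfig | None = None,
    stages: dict | None = None,
) -> LabelMap:
    """Seed selection + watershed on an already pre-processed image.

    This is the pipeline downstream of pre-processing, shared verbatim
    by the bilateral-enabled and bilateral-disabled arms.
    """
    if cfg is None:
        cfg = PipelineConfig()
    sp = cfg.seeds
    shape = (pre.height, pre.width)

    def record(name, arr):
        if stages is not None:
            stages[name] = np.array(arr, copy=True)

    empty = LabelMap(np.zeros(shape, dtype=np.int64))
    try:
        raw_mask = otsu_threshold(pre)
    except DegenerateImageError:
        record("foreground_raw", np.zeros(shape, dtype=bool))
        record("labels", empty.labels)
        return empty
    record("foreground_raw", raw_mask.pixels)
    refined = refine_mask(raw_mask, sp)
    record("foreground", refined.pixels)
    if not refined.pixels.any():
        record("labels", empty.labels)
        return empty

    dmap = distance_transform(refined, sp.edt_mask,
                              border_is_background=sp.border_is_background)
    record("distance", dmap.values)
    ndmap = normalize_distance(dmap)
    record("distance_normalized", ndmap.values)
    maxima = regional_maxima(ndmap, sp.maxima_window)
    record("maxima", maxima.pixels)
    seeds = seeds_from_maxima(maxima, sp.dilate_radius)
    record("markers", seeds.markers)
    if seeds.K == 0:
        record("labels", empty.labels)
        return empty

    edges = laplacian_edges(pre)
    record("edges", edges)
    labels = marker_watershed(edges, seeds, mask=refined.pixels)
    clipped = labels.labels.copy()
    clipped[~refined.pixels] = 0  # clip basins to the refined foreground
    result = LabelMap(clipped).compact()
    if cfg.watershed.boundary_lines:
        result = draw_boundary_lines(result)
    record("labels", result.labels)
    return result


def segment_stages(img: GrayImage, cfg: PipelineConfig | None = None) -> dict:
    """Run the full pipeline capturing every intermediate stage array."""
    if cfg is None:
        cfg = PipelineConfig()
    stages: dict[str, np.ndarray] = {}
    pre = preprocess_image(img, cfg)
    stages["preprocessed"] = np.array(pre.pixels, copy=True)
    instances_from_preprocessed(pre, cfg, stages=stages)
    return stages


def segment_image(img: GrayImage, cfg: PipelineConfig | None = None) -> LabelMap:
    """Full pipeline: pre-process, select seeds, flood, count-ready labels.

    Degenerate inputs (e.g. a constant frame) yield an empty label map.
    """
    if cfg is None:
        cfg = PipelineConfig()
    pre = preprocess_image(img, cfg)
    return instances_from_preprocessed(pre, cfg)


def count_cells(label_map: LabelMap) -> int:
    """Number of distinct positive labels (the automated cell count)."""
    return label_map.n_labels
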