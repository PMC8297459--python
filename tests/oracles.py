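"""Independent brute-force reference implementations.

Every function here evaluates its operator straight from the
definition with explicit loops or exhaustive search, sharing no code
with the package implementation. They are intended for small inputs
(~15x15) only.
"""

from __future__ import annotations

import math

import numpy as np


def disk(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    return (ax[:, None] ** 2 + ax[None, :] ** 2) <= radius * radius


def bilateral_brute(I: np.ndarray, sigma_c: float, sigma_s: float, radius: int) -> np.ndarray:
    """Double-loop weighted mean over the in-image square window."""
    h, w = I.shape
    out = np.empty((h, w), dtype=float)
    for i in range(h):
        for j in range(w):
            num = den = 0.0
            for qi in range(max(0, i - radius), min(h, i + radius + 1)):
                for qj in range(max(0, j - radius), min(w, j + radius + 1)):
                    c = math.exp(-0.5 * ((i - qi) ** 2 + (j - qj) ** 2) / sigma_s**2)
                    s = math.exp(-0.5 * ((I[i, j] - I[qi, qj]) / sigma_c) ** 2)
                    num += c * s * I[qi, qj]
                    den += c * s
            out[i, j] = num / den
    return out


def _grey_erode_brute(I: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    h, w = I.shape
    r = footprint.shape[0] // 2
    out = np.empty_like(I, dtype=float)
    for i in range(h):
        for j in range(w):
            best = math.inf
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if not footprint[di + r, dj + r]:
                        continue
                    qi, qj = i + di, j + dj
                    if 0 <= qi < h and 0 <= qj < w:
                        best = min(best, I[qi, qj])
            out[i, j] = best
    return out


def _grey_dilate_brute(I: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return -_grey_erode_brute(-I, footprint[::-1, ::-1])


def white_tophat_brute(I: np.ndarray, radius: int) -> np.ndarray:
    """Image minus its opening (erosion then dilation) by a flat disk."""
    fp = disk(radius)
    return I - _grey_dilate_brute(_grey_erode_brute(I, fp), fp)


def binary_erode_brute(mask: np.ndarray, radius: int) -> np.ndarray:
    """All in-image footprint samples must be foreground."""
    return _grey_erode_brute(mask.astype(float), disk(radius)) > 0.5


def binary_dilate_brute(mask: np.ndarray, radius: int) -> np.ndarray:
    return _grey_dilate_brute(mask.astype(float), disk(radius)) > 0.5


def binary_open_brute(mask: np.ndarray, radius: int) -> np.ndarray:
    return binary_dilate_brute(binary_erode_brute(mask, radius), radius)


def binary_close_brute(mask: np.ndarray, radius: int) -> np.ndarray:
    return binary_erode_brute(binary_dilate_brute(mask, radius), radius)


def fill_holes_brute(mask: np.ndarray) -> np.ndarray:
    """Flood the background 4-connectedly from the border; the rest fills."""
    h, w = mask.shape
    reach = np.zeros((h, w), dtype=bool)
    stack = [(i, j) for i in range(h) for j in range(w)
             if (i in (0, h - 1) or j in (0, w - 1)) and not mask[i, j]]
    for i, j in stack:
        reach[i, j] = True
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            qi, qj = i + di, j + dj
            if 0 <= qi < h and 0 <= qj < w and not mask[qi, qj] and not reach[qi, qj]:
                reach[qi, qj] = True
                stack.append((qi, qj))
    return mask | ~reach


def otsu_brute(values: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive between-class-variance scan over the shared histogram
    contract (n_bins equal bins over [min, max]); returns the threshold."""
    flat = values.ravel().astype(float)
    lo, hi = flat.min(), flat.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    idx = np.minimum(((flat - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
    best_sigma, best_t = -1.0, centers[0]
    for k in range(n_bins - 1):
        lowc = idx <= k
        n0, n1 = lowc.sum(), (~lowc).sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = centers[idx[lowc]].mean()
        mu1 = centers[idx[~lowc]].mean()
        sigma_b = n0 * n1 * (mu0 - mu1) ** 2
        if sigma_b > best_sigma:  # strict: ties keep the lowest threshold
            best_sigma, best_t = sigma_b, centers[k]
    return best_t


def exact_edt_brute(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance to nearest background by exhaustive search."""
    h, w = mask.shape
    bg = np.argwhere(~mask)
    out = np.zeros((h, w), dtype=float)
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                d2 = ((bg[:, 0] - i) ** 2 + (bg[:, 1] - j) ** 2).min()
                out[i, j] = math.sqrt(d2)
    return out


def regional_maxima_brute(values: np.ndarray, window: int) -> np.ndarray:
    """Plateau/boundary check from the definition under window adjacency."""
    h, w = values.shape
    r = window // 2
    seen = np.zeros((h, w), dtype=bool)
    out = np.zeros((h, w), dtype=bool)
    for si in range(h):
        for sj in range(w):
            if seen[si, sj] or values[si, sj] <= 0:
                continue
            v = values[si, sj]
            comp = [(si, sj)]
            seen[si, sj] = True
            is_max = True
            head = 0
            while head < len(comp):
                i, j = comp[head]
                head += 1
                for di in range(-r, r + 1):
                    for dj in range(-r, r + 1):
                        qi, qj = i + di, j + dj
                        if not (0 <= qi < h and 0 <= qj < w) or (qi, qj) == (i, j):
                            continue
                        if values[qi, qj] == v:
                            if not seen[qi, qj]:
                                seen[qi, qj] = True
                                comp.append((qi, qj))
                        elif values[qi, qj] > v:
                            is_max = False
            if is_max:
                for i, j in comp:
                    out[i, j] = True
    return out


def marker_watershed_brute(
    edges: np.ndarray, markers: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Naive flood simulation: a plain list as the priority queue,
    scanned linearly for the (value, insertion order) minimum."""
    h, w = edges.shape
    out = markers.astype(np.int64).copy()
    domain = np.ones((h, w), bool) if mask is None else (np.asarray(mask, bool) | (markers > 0))
    queue: list[tuple[float, int, int, int, int]] = []
    counter = 0
    for i in range(h):
        for j in range(w):
            if markers[i, j] > 0:
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    qi, qj = i + di, j + dj
                    if 0 <= qi < h and 0 <= qj < w and domain[qi, qj] and out[qi, qj] == 0:
                        queue.append((edges[qi, qj], counter, qi, qj, int(markers[i, j])))
                        counter += 1
    while queue:
        best = min(range(len(queue)), key=lambda k: (queue[k][0], queue[k][1]))
        _, _, i, j, lab = queue.pop(best)
        if out[i, j] != 0:
            continue
        out[i, j] = lab
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            qi, qj = i + di, j + dj
            if 0 <= qi < h and 0 <= qj < w and domain[qi, qj] and out[qi, qj] == 0:
                queue.append((edges[qi, qj], counter, qi, qj, lab))
                counter += 1
    return out
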