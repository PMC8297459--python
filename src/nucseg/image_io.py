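"""Raster containers and file I/O.

The pipeline's working currency is a single-channel gray-scale raster.
Intensities are kept as stored integers on disk; once pre-processing
starts they are carried at float precision (bilateral weights and the
distance transform are real-valued).

Conventions fixed here once and used everywhere:

* arrays are row-major, indexed ``(row, col)``, 0-based;
* label maps use 0 for background and ``1..K`` for instances;
* 16-bit containers whose maximum value fits in 12 bits are flagged as
  12-bit data (a common camera convention), overridable by the caller.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "GrayImage",
    "BinaryMask",
    "LabelMap",
    "read_image",
    "write_image",
    "read_label_map",
    "write_label_map",
]

_VALID_DEPTHS = (8, 12, 16)


class ImageIOError(ValueError):
    """Unreadable, unwritable or unsupported raster input."""


@dataclass
class GrayImage:
    """2-D single-channel intensity raster with bit-depth metadata."""

    pixels: np.ndarray
    bit_depth: int = 8
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        if self.bit_depth not in _VALID_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_VALID_DEPTHS}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        """Top of the dynamic range, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    def validate(self) -> None:
        if self.pixels.min() < 0 or self.pixels.max() > self.max_value:
            raise ValueError(
                f"intensities outside [0, {self.max_value}] for "
                f"{self.bit_depth}-bit image"
            )


@dataclass
class BinaryMask:
    """2-D boolean raster marking candidate foreground."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask requires a 2-D array")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class LabelMap:
    """2-D integer raster; 0 = background, k > 0 = nucleus instance k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMap requires a 2-D array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = self.labels.astype(np.int64, copy=False)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def n_labels(self) -> int:
        """Number of distinct positive labels."""
        positive = np.unique(self.labels)
        return int((positive > 0).sum())

    def compact(self) -> "LabelMap":
        """Renumber positive labels to the gap-free set ``1..K``."""
        values = np.unique(self.labels)
        values = values[values > 0]
        lut = np.zeros(int(self.labels.max()) + 1, dtype=np.int64)
        lut[values] = np.arange(1, values.size + 1)
        return LabelMap(lut[self.labels])


def _as_gray_array(img) -> np.ndarray:
    if isinstance(img, GrayImage):
        return img.pixels
    return np.asarray(img)


def _infer_bit_depth(arr: np.ndarray) -> int:
    """Infer bit depth from dtype, flagging 12-in-16-bit data by max value."""
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 12 if int(arr.max(initial=0)) <= 4095 else 16
    raise ImageIOError(f"unsupported pixel dtype {arr.dtype}")


def read_image(path: str | os.PathLike, bit_depth: int | None = None) -> GrayImage:
    """Read a TIFF/PNG image into a :class:`GrayImage`.

    Multi-channel inputs are collapsed only when all channels are
    identical (replicated gray); genuinely colored inputs raise
    :class:`ImageIOError` — the caller must pre-split channels.

    Parameters
    ----------
    path
        Readable TIFF or PNG file.
    bit_depth
        Override the inferred bit depth (e.g. force 16 on 12-bit-looking
        data, or assert the 12-in-16-bit convention).
    """
    path = os.fspath(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - wrap any backend failure
        raise ImageIOError(f"cannot read image {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] in (2, 4):  # drop alpha if the rest is replicated
            arr = arr[..., :-1]
        if arr.shape[2] == 1:
            arr = arr[..., 0]
        elif np.all(arr[..., 1:] == arr[..., :1]):
            arr = arr[..., 0]
        else:
            raise ImageIOError(
                f"{path!r} is genuinely multi-channel; split channels first"
            )
    if arr.ndim != 2:
        raise ImageIOError(f"{path!r} is not a 2-D raster (shape {arr.shape})")
    depth = bit_depth if bit_depth is not None else _infer_bit_depth(arr)
    img = GrayImage(arr, bit_depth=depth, source_path=path)
    img.validate()
    return img


def write_image(img: GrayImage, path: str | os.PathLike) -> None:
    """Write a :class:`GrayImage` to TIFF or PNG (by extension).

    8-bit data is stored as uint8; 12- and 16-bit data as uint16.
    Read-back through :func:`read_image` is pixel-identical.
    """
    path = os.fspath(path)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    arr = np.round(np.asarray(img.pixels)).astype(dtype)
    _write_array(arr, path)


def _write_array(arr: np.ndarray, path: str) -> None:
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            tifffile.imwrite(path, arr)
        else:
            iio.imwrite(path, arr)
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"cannot write {path!r}: {exc}") from exc


def write_label_map(label_map: LabelMap, path: str | os.PathLike) -> None:
    """Write a label map as a single-channel integer raster.

    Uses a 16-bit container when the maximum label fits, otherwise a
    32-bit TIFF (PNG has no 32-bit gray mode). 16-bit PNG bytes are
    deterministic, which the batch runner's reproducibility contract
    relies on.
    """
    path = os.fspath(path)
    max_label = int(label_map.labels.max(initial=0))
    if max_label <= 0xFFFF:
        arr = label_map.labels.astype(np.uint16)
    else:
        arr = label_map.labels.astype(np.uint32)
        ext = os.path.splitext(path)[1].lower()
        if ext not in (".tif", ".tiff"):
            raise ImageIOError(
                f"{max_label} labels need a 32-bit container; use TIFF"
            )
    _write_array(arr, path)


def read_label_map(path: str | os.PathLike) -> LabelMap:
    """Read a label map written by :func:`write_label_map`."""
    path = os.fspath(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"cannot read label map {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ImageIOError(f"label map {path!r} is not single-channel")
    return LabelMap(arr)
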