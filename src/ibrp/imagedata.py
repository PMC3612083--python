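"""Core raster types and file I/O.

Pixel data are kept in camera units throughout — there is no automatic
rescaling to [0, 1].  Exposure-time normalization must operate on raw
proportional counts, so every normalization step downstream is explicit.

Conventions: coordinates are 0-based, row-major, origin at the top-left
corner.  Exposure time is supplied by the caller (or a config/manifest),
never parsed from TIFF tags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import (
    EmptyTableError,
    ImageReadError,
    InvalidExposureError,
    NotGrayscaleError,
    ShapeMismatchError,
)

__all__ = [
    "GrayImage",
    "LabelMap",
    "read_image",
    "write_image",
    "write_overlay",
    "write_measurements",
    "read_measurements",
    "MEASUREMENT_COLUMNS",
]

_DTYPE_FOR_DEPTH = {8: np.uint8, 12: np.uint16, 16: np.uint16}


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale intensity raster with acquisition metadata.

    Parameters
    ----------
    pixels
        Non-negative intensities in camera units, shape (rows, cols).
    bit_depth
        Camera bit depth (8, 12 or 16).  12-bit data stored in 16-bit
        containers are accepted; values above ``2**bit_depth - 1`` only
        trigger a warning.
    exposure_ms
        Exposure time in milliseconds; must be positive whenever
        exposure normalization is requested.
    pixel_size_um
        Physical size of one pixel at the sample plane, in micrometres.
    channel_tag
        Free-form label such as ``"GFP"`` or ``"phase"``.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    exposure_ms: float | None = None
    pixel_size_um: float | None = None
    channel_tag: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise NotGrayscaleError(
                f"expected a 2-D raster, got shape {px.shape}"
            )
        if px.size == 0:
            raise ImageReadError("empty raster")
        if np.any(px < 0):
            raise ImageReadError("negative pixel values are not allowed")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        if px.max() > self.max_value:
            warnings.warn(
                f"pixel values exceed 2**{self.bit_depth} - 1; "
                "check the configured bit depth",
                stacklevel=3,
            )
        object.__setattr__(self, "pixels", px)
        if self.exposure_ms is not None and self.exposure_ms <= 0:
            raise InvalidExposureError(
                f"exposure_ms must be > 0, got {self.exposure_ms}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        """Largest representable camera value, ``2**bit_depth - 1``."""
        return 2 ** self.bit_depth - 1

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Return a copy carrying the same metadata but new pixel data."""
        return replace(self, pixels=pixels)

    def require_exposure(self) -> float:
        if self.exposure_ms is None or self.exposure_ms <= 0:
            raise InvalidExposureError(
                "operation requires a positive exposure_ms"
            )
        return float(self.exposure_ms)


@dataclass(frozen=True)
class LabelMap:
    """Integer particle labels on the image grid; 0 is background."""

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ShapeMismatchError("label map must be 2-D")
        if not np.issubdtype(lab.dtype, np.integer):
            raise TypeError("labels must be integers")
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", lab.astype(np.int32))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def label_values(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]

    def compact(self) -> "LabelMap":
        """Relabel so the label set is a contiguous {0..K}."""
        vals = self.label_values
        out = np.zeros_like(self.labels)
        for new, old in enumerate(vals, start=1):
            out[self.labels == old] = new
        return LabelMap(out)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def read_image(
    path: str | Path,
    exposure_ms: float,
    pixel_size_um: float | None = None,
    bit_depth: int | None = None,
    channel_tag: str = "",
) -> GrayImage:
    """Read a single-plane grayscale TIFF (or PNG fixture).

    Integer data are kept in camera units — no rescaling.  ``bit_depth``
    defaults to the container depth (uint8 -> 8, uint16 -> 16).
    """
    path = Path(path)
    if exposure_ms is None or exposure_ms <= 0:
        raise InvalidExposureError(
            f"exposure_ms must be > 0, got {exposure_ms}"
        )
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except InvalidExposureError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader failures
        raise ImageReadError(f"cannot read {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise NotGrayscaleError(
            f"{path} is not single-channel grayscale (shape {arr.shape})"
        )
    if bit_depth is None:
        bit_depth = 8 if arr.dtype == np.uint8 else 16
    return GrayImage(
        pixels=arr,
        bit_depth=bit_depth,
        exposure_ms=exposure_ms,
        pixel_size_um=pixel_size_um,
        channel_tag=channel_tag,
    )


def write_image(img: GrayImage, path: str | Path) -> Path:
    """Write pixels losslessly at the image's container depth."""
    path = Path(path)
    dtype = _DTYPE_FOR_DEPTH[img.bit_depth]
    data = np.clip(np.rint(img.pixels), 0, np.iinfo(dtype).max).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)
    return path


def write_labelmap(labels: LabelMap, path: str | Path) -> Path:
    """Write a label map as a 16-bit TIFF."""
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.uint16))
    return path


# 3x5 bitmap digit glyphs for label annotation in overlays.
_DIGITS = {
    "0": ["111", "101", "101", "101", "111"],
    "1": ["010", "110", "010", "010", "111"],
    "2": ["111", "001", "111", "100", "111"],
    "3": ["111", "001", "111", "001", "111"],
    "4": ["101", "101", "111", "001", "001"],
    "5": ["111", "100", "111", "001", "111"],
    "6": ["111", "100", "111", "101", "111"],
    "7": ["111", "001", "010", "010", "010"],
    "8": ["111", "101", "111", "101", "111"],
    "9": ["111", "101", "111", "001", "111"],
}


def _draw_number(rgb: np.ndarray, row: int, col: int, text: str, color) -> None:
    r0 = row - 2
    c0 = col - (len(text) * 4 - 1) // 2
    for ch in text:
        glyph = _DIGITS.get(ch)
        if glyph is None:
            c0 += 4
            continue
        for dr, line in enumerate(glyph):
            for dc, bit in enumerate(line):
                if bit == "1":
                    rr, cc = r0 + dr, c0 + dc
                    if 0 <= rr < rgb.shape[0] and 0 <= cc < rgb.shape[1]:
                        rgb[rr, cc] = color
        c0 += 4


def write_overlay(
    img: GrayImage,
    labels: LabelMap,
    path: str | Path,
    outline_color=(255, 0, 255),
) -> Path:
    """Write an RGB check image: rescaled grayscale base, particle
    outlines in a contrasting color, label numbers at the centroids."""
    from scipy import ndimage as ndi
    from skimage.segmentation import find_boundaries

    if img.shape != labels.shape:
        raise ShapeMismatchError(
            f"image {img.shape} vs labels {labels.shape}"
        )
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    scale = (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)
    base = (scale * 255).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    lab = labels.labels
    if labels.n_labels:
        edges = find_boundaries(lab, mode="outer") & (lab == 0) | find_boundaries(
            lab, mode="inner"
        )
        rgb[edges] = outline_color
        for value in labels.label_values:
            cr, cc = ndi.center_of_mass(lab == value)
            _draw_number(rgb, int(round(cr)), int(round(cc)), str(int(value)),
                         outline_color)
    path = Path(path)
    iio.imwrite(path, rgb)
    return path


MEASUREMENT_COLUMNS = [
    "condition",
    "bead_id",
    "area_px",
    "circularity",
    "mean_intensity_raw",
    "mean_intensity_corrected",
    "intensity_per_ms",
]


def write_measurements(
    rows: Iterable[Mapping] | pd.DataFrame, path: str | Path
) -> Path:
    """Write the per-bead measurement table as CSV.

    Row order is deterministic: by condition, then bead_id.  Values are
    written with 9 significant digits so re-runs are byte-identical.
    """
    df = pd.DataFrame(rows)
    if df.empty:
        raise EmptyTableError("no measurement rows to write")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing measurement columns: {missing}")
    df = (
        df[MEASUREMENT_COLUMNS]
        .sort_values(["condition", "bead_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
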