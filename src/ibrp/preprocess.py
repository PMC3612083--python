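"""Denoising and uneven-illumination removal.

The two steps mirror the standard mask-preparation recipe for bead
fluorescence images: a small Gaussian filter to suppress shot noise,
then rolling-ball background subtraction to flatten the slowly varying
illumination field left by an air objective.

The rolling-ball background is the envelope traced by the top of a ball
of radius ``r`` rolled beneath the intensity surface — mathematically, a
grayscale opening with the spherical-cap structuring function
``b(x, y) = sqrt(r^2 - x^2 - y^2)``.  Exact opening costs O(r^2) per
pixel, so for large radii the image is shrunk, opened at the reduced
radius, and the background interpolated back up; the interpolated
background is clipped to the image so it remains a lower envelope.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .imagedata import GrayImage

__all__ = [
    "gaussian_smooth",
    "subtract_background",
    "rolling_ball_background",
    "ball_structuring_element",
]

#: Largest radius opened exactly; beyond this the shrink path is used.
MAX_DIRECT_RADIUS = 64
#: Effective radius targeted by the shrink path.
SHRUNK_TARGET_RADIUS = 32


def gaussian_smooth(img: GrayImage, radius_px: float = 1.0) -> GrayImage:
    """Gaussian-filter the image with sigma = ``radius_px``.

    The kernel is truncated at 4 sigma.  ``radius_px = 0`` returns an
    identical copy.  Total intensity is conserved for signals supported
    away from the border (the filter is normalized).
    """
    if radius_px < 0:
        raise ValueError(f"radius_px must be >= 0, got {radius_px}")
    if radius_px == 0:
        return img.with_pixels(img.pixels.copy())
    smoothed = ndi.gaussian_filter(
        img.pixels, sigma=radius_px, truncate=4.0, mode="reflect"
    )
    return img.with_pixels(smoothed)


def ball_structuring_element(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile of a ball of the given radius.

    Returns ``(footprint, heights)`` where ``heights[y, x] =
    sqrt(r^2 - x^2 - y^2)`` inside the footprint.
    """
    if radius < 1:
        raise ValueError(f"ball radius must be >= 1, got {radius}")
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = (x * x + y * y).astype(np.float64)
    footprint = d2 <= radius * radius
    heights = np.zeros_like(d2)
    heights[footprint] = np.sqrt(radius * radius - d2[footprint])
    return footprint, heights


def _open_with_ball(pixels: np.ndarray, radius: float) -> np.ndarray:
    footprint, heights = ball_structuring_element(radius)
    eroded = ndi.grey_erosion(
        pixels, footprint=footprint, structure=heights, mode="reflect"
    )
    return ndi.grey_dilation(
        eroded, footprint=footprint, structure=heights, mode="reflect"
    )


def rolling_ball_background(
    pixels: np.ndarray, ball_radius_px: float
) -> np.ndarray:
    """Estimate the smooth background under ``pixels``.

    Radii up to ``MAX_DIRECT_RADIUS`` are opened exactly; larger radii
    use the shrink approximation.  The result never exceeds the input
    (lower-envelope contract).
    """
    if ball_radius_px < 1:
        raise ValueError(
            f"ball_radius_px must be >= 1, got {ball_radius_px}"
        )
    pixels = np.asarray(pixels, dtype=np.float64)
    if ball_radius_px <= MAX_DIRECT_RADIUS:
        return _open_with_ball(pixels, ball_radius_px)
    shrink = int(np.ceil(ball_radius_px / SHRUNK_TARGET_RADIUS))
    small_shape = (
        max(2, int(np.ceil(pixels.shape[0] / shrink))),
        max(2, int(np.ceil(pixels.shape[1] / shrink))),
    )
    small = resize(
        pixels, small_shape, order=1, anti_aliasing=True, mode="reflect"
    )
    small_bg = _open_with_ball(small, ball_radius_px / shrink)
    background = resize(small_bg, pixels.shape, order=3, mode="reflect")
    # interpolation can overshoot locally; keep the envelope property
    return np.minimum(background, pixels)


def subtract_background(
    img: GrayImage, ball_radius_px: float = 400.0
) -> tuple[GrayImage, GrayImage]:
    """Rolling-ball background subtraction.

    Returns ``(corrected, background)``.  ``corrected = img - background``
    clipped at zero (negative fluorescence is non-physical), and
    ``background`` is a smooth lower envelope of the image.
    """
    background = rolling_ball_background(img.pixels, ball_radius_px)
    corrected = np.clip(img.pixels - background, 0.0, None)
    # an opening can dip below zero next to isolated dark pixels; the
    # background raster itself must stay a valid non-negative image
    background = np.clip(background, 0.0, None)
    return img.with_pixels(corrected), img.with_pixels(background)
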