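"""Per-bead intensity measurement and normalized binding affinity.

The measurement chain per bead is:

1. mean intensity over the bead mask, on the background-subtracted
   fluorescence image (``mean_intensity_raw``);
2. minus the autofluorescence of blank (bait-free) beads, floored at 0
   (``mean_intensity_corrected``);
3. divided by the exposure time in ms (``intensity_per_ms``).

The prey input is the exposure-normalized mean fluorescence of the
lysate well minus that of a mock-transfected lysate.  The binding
affinity of one condition is then the per-bead ``intensity_per_ms``
further divided by prey input and bait input — a relative measure of
interaction strength that is invariant to exposure time and to the
loadings of both binding partners.  For plotting, affinities within a
comparison set are rescaled so the maximum is 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .errors import NormalizationError, ShapeMismatchError
from .imagedata import GrayImage, LabelMap
from .segmentation import Particle

__all__ = [
    "BeadMeasurement",
    "AssayCondition",
    "AffinityResult",
    "PreyInput",
    "measure_beads",
    "measure_lysate_input",
    "ibrp_affinity",
    "relative_affinities",
    "snr",
]


@dataclass(frozen=True)
class BeadMeasurement:
    """Corrected, exposure-normalized mean intensity of one bead."""

    particle_label: int
    area_px: int
    circularity: float
    mean_intensity_raw: float
    mean_intensity_corrected: float
    intensity_per_ms: float
    floored: bool = False
    saturated: bool = False


@dataclass(frozen=True)
class PreyInput:
    """Exposure-normalized, mock-corrected lysate fluorescence."""

    per_ms: float
    floored: bool = False


@dataclass(frozen=True)
class AssayCondition:
    """One bait x prey pull-down with its bead measurements.

    ``bait_input`` is the bait density on beads (ug/ul or uM, treated as
    an opaque positive scalar); ``prey_input_per_ms`` the lysate
    fluorescence per ms.  When a comparison set shares the same bait or
    prey, that input may simply be set to 1.
    """

    condition_id: str
    measurements: list[BeadMeasurement]
    bait_input: float = 1.0
    prey_input_per_ms: float = 1.0
    exposure_ms: float | None = None
    bait_unit: str = ""

    @property
    def n(self) -> int:
        return len(self.measurements)


@dataclass(frozen=True)
class AffinityResult:
    """Binding affinity of one condition: mean, SD and bead count."""

    condition_id: str
    affinity_mean: float
    affinity_sd: float
    n: int
    per_bead: tuple[float, ...]
    relative_affinity: float | None = None
    relative_sd: float | None = None


def measure_beads(
    corrected_img: GrayImage,
    labels: LabelMap,
    particles: list[Particle],
    blank_autofluorescence: float = 0.0,
    *,
    saturation_img: GrayImage | None = None,
    saturation_policy: str = "exclude",
) -> list[BeadMeasurement]:
    """Measure every particle on the background-subtracted image.

    ``blank_autofluorescence`` (camera units, on the same corrected
    scale) is subtracted from each bead mean; negatives floor at 0 and
    are flagged.  Saturation is judged on ``saturation_img`` (the
    pre-subtraction raster) when given: beads containing pixels at
    ``2**bit_depth - 1`` break the linearity the assay depends on and
    are excluded by default (policy ``"exclude"``; ``"flag"`` keeps
    them, ``"ignore"`` skips the check).
    """
    if blank_autofluorescence < 0:
        raise ValueError("blank_autofluorescence must be >= 0")
    if saturation_policy not in ("exclude", "flag", "ignore"):
        raise ValueError(f"unknown saturation policy {saturation_policy!r}")
    if corrected_img.shape != labels.shape:
        raise ShapeMismatchError(
            f"image {corrected_img.shape} vs labels {labels.shape}"
        )
    exposure = corrected_img.require_exposure()
    lab = labels.labels
    sat_mask = None
    if saturation_policy != "ignore" and saturation_img is not None:
        sat_mask = saturation_img.pixels >= saturation_img.max_value
    out: list[BeadMeasurement] = []
    for p in particles:
        member = lab == p.label
        n_px = int(member.sum())
        if n_px == 0:
            raise ValueError(f"particle {p.label} has no member pixels")
        raw = float(corrected_img.pixels[member].mean())
        corrected = raw - blank_autofluorescence
        floored = corrected < 0
        if floored:
            corrected = 0.0
        saturated = bool(sat_mask[member].any()) if sat_mask is not None else False
        if saturated and saturation_policy == "exclude":
            continue
        out.append(
            BeadMeasurement(
                particle_label=p.label,
                area_px=n_px,
                circularity=p.circularity,
                mean_intensity_raw=raw,
                mean_intensity_corrected=corrected,
                intensity_per_ms=corrected / exposure,
                floored=floored,
                saturated=saturated,
            )
        )
    return out


def measure_lysate_input(
    lysate_img: GrayImage, mock_img: GrayImage | None = None
) -> PreyInput:
    """Prey input: exposure-normalized lysate mean, mock-corrected.

    ``(mean(lysate)/exposure) - (mean(mock)/exposure_mock)``, floored at
    0 with a flag when the mock is at least as bright as the lysate.
    """
    value = float(lysate_img.pixels.mean()) / lysate_img.require_exposure()
    if mock_img is not None:
        value -= float(mock_img.pixels.mean()) / mock_img.require_exposure()
    floored = value < 0 or value == 0
    return PreyInput(per_ms=max(value, 0.0), floored=floored)


def ibrp_affinity(condition: AssayCondition) -> AffinityResult:
    """Affinity of one condition from its per-bead measurements.

    Per bead ``a_i = intensity_per_ms_i / (prey_input_per_ms *
    bait_input)``; the condition affinity is the mean of the ``a_i``
    with the sample SD (n-1 denominator).  Per-bead values are kept so
    downstream tests (Welch t) see the full dispersion.
    """
    if condition.bait_input <= 0:
        raise NormalizationError(
            f"bait_input must be > 0, got {condition.bait_input}"
        )
    if condition.prey_input_per_ms <= 0:
        raise NormalizationError(
            f"prey_input_per_ms must be > 0, got {condition.prey_input_per_ms}"
        )
    if condition.n < 1:
        raise ValueError("condition has no bead measurements")
    denom = condition.prey_input_per_ms * condition.bait_input
    per_bead = tuple(
        m.intensity_per_ms / denom for m in condition.measurements
    )
    arr = np.asarray(per_bead)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return AffinityResult(
        condition_id=condition.condition_id,
        affinity_mean=float(arr.mean()),
        affinity_sd=sd,
        n=arr.size,
        per_bead=per_bead,
    )


def relative_affinities(results: list[AffinityResult]) -> list[AffinityResult]:
    """Rescale a comparison set so the largest mean affinity is 100.

    SDs are scaled by the same factor, so relative error bars are
    preserved.
    """
    if not results:
        raise ValueError("no affinity results")
    top = max(r.affinity_mean for r in results)
    if top <= 0:
        raise NormalizationError("all affinity means are zero")
    # divide by the top mean (rather than premultiplying 100/top) so the
    # maximum is exactly 100.0 in floating point: top/top == 1.0
    return [
        replace(
            r,
            relative_affinity=r.affinity_mean / top * 100.0,
            relative_sd=r.affinity_sd / top * 100.0,
        )
        for r in results
    ]


def snr(
    corrected_img: GrayImage, labels: LabelMap, dilation_px: int = 3
) -> float:
    """Signal-to-noise ratio of a bead field.

    Mean intensity over all bead pixels divided by the standard
    deviation of the background.  Background pixels are those outside
    every particle mask after dilating the masks by ``dilation_px`` to
    keep bead rims and halos out of the noise estimate.
    """
    if corrected_img.shape != labels.shape:
        raise ShapeMismatchError("image and label shapes differ")
    fg = labels.labels > 0
    if not fg.any():
        raise ValueError("no particles in label map")
    if dilation_px > 0:
        structure = np.ones((3, 3), bool)
        dilated = ndi.binary_dilation(fg, structure, iterations=dilation_px)
    else:
        dilated = fg
    background = ~dilated
    if background.sum() < 100:
        raise ValueError("fewer than 100 background pixels")
    bg_sd = float(corrected_img.pixels[background].std(ddof=1))
    if bg_sd == 0:
        raise ZeroDivisionError("zero background variance")
    return float(corrected_img.pixels[fg].mean()) / bg_sd
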