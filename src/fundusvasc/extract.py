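"""Grayscale channel filters, vessel extraction, and optic-disc localization.

Vessels are extracted from the green channel (best vessel/background
contrast); the HSV value channel is used only to find the bright optic disc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .config import DiscParams, ExtractParams
from .errors import DetectionError, InvalidSpecError
from .io import FundusImage, RoiMask


@dataclass
class GrayImage:
    """A uint8 scalar grid with the provenance of its conversion."""

    values: np.ndarray
    provenance: str  # hsv_value | red_free | green_only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)


@dataclass
class VesselMap:
    """Binary vessel grid confined to an ROI."""

    mask: np.ndarray
    roi: RoiMask

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.roi.shape:
            raise InvalidSpecError("vessel map and ROI shapes differ")
        # containment is a class invariant, enforce rather than trust
        self.mask &= self.roi.mask

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class OpticDisc:
    center: tuple[float, float]  # (row, col)
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidSpecError("optic disc radius must be positive")


def hsv_value_channel(img: FundusImage) -> GrayImage:
    """HSV value channel: per-pixel max(R, G, B)."""
    return GrayImage(img.pixels.max(axis=2), "hsv_value")


def red_free_gray(img: FundusImage) -> GrayImage:
    """Red-free grayscale: round((G + B) / 2), red channel discarded."""
    g = img.pixels[:, :, 1].astype(np.uint16)
    b = img.pixels[:, :, 2].astype(np.uint16)
    return GrayImage(((g + b + 1) // 2).astype(np.uint8), "red_free")


def green_only_gray(img: FundusImage) -> GrayImage:
    """Green channel alone, where vessel/background contrast is strongest."""
    return GrayImage(img.pixels[:, :, 1], "green_only")


def extract_vessels(
    img: FundusImage,
    roi: RoiMask,
    params: ExtractParams | None = None,
    disc: OpticDisc | None = None,
) -> VesselMap:
    """Edge-detection-based vessel extraction within an ROI.

    Pipeline: (1) green-only grayscale; (2) background flattening by
    subtracting a large-window local average; (3) gradient-magnitude edge
    detection with hysteresis thresholds taken at percentiles of the gradient
    inside the ROI; (4) morphological closing of the paired vessel edges and
    hole filling to solid vessel bodies, then trimming the halo of edge
    pixels brighter than the flattened background (vessels are dark, so true
    vessel pixels sit below it); (5) removal of components smaller than
    ``params.min_component_px`` and, when the optic disc is known, of the
    disc area whose bright rim would otherwise close into a false blob;
    (6) intersection with the ROI.
    """
    params = params or ExtractParams()
    if roi.area == 0:
        raise InvalidSpecError("ROI is empty")
    if roi.shape != img.shape:
        raise InvalidSpecError("ROI shape does not match image")

    gray = green_only_gray(img).values.astype(np.float64)
    rows, cols = gray.shape
    win = max(3, int(min(rows, cols) * params.local_window_frac))
    if win % 2 == 0:
        win += 1
    background = ndimage.uniform_filter(gray, size=win, mode="reflect")
    flat = gray - background

    grad = filters.sobel(flat)
    inside = grad[roi.mask]
    lo = np.percentile(inside, params.hysteresis_low_pct)
    hi = np.percentile(inside, params.hysteresis_high_pct)
    if hi <= 0:  # featureless image: no gradient anywhere
        return VesselMap(np.zeros_like(roi.mask), roi)
    edges = filters.apply_hysteresis_threshold(grad, lo, hi)

    closed = morphology.closing(edges, morphology.disk(params.close_radius))
    solid = ndimage.binary_fill_holes(closed)
    # vessels are darker than the flattened background: trim the bright halo
    # of edge pixels using the Otsu cut between the two intensity modes
    solid &= flat < filters.threshold_otsu(flat[roi.mask])

    if disc is not None:
        rr = np.arange(rows)[:, None] - disc.center[0]
        cc = np.arange(cols)[None, :] - disc.center[1]
        solid &= rr * rr + cc * cc > (1.2 * disc.radius) ** 2
    solid = morphology.remove_small_objects(solid, max_size=params.min_component_px - 1)
    return VesselMap(solid & roi.mask, roi)


def detect_optic_disc(img: FundusImage, params: DiscParams | None = None) -> OpticDisc:
    """Locate the optic disc as the largest very-bright blob.

    The HSV value channel is thresholded at its ``value_percentile``; the
    centroid of the largest connected component above it gives the center and
    its equivalent-circle radius the disc radius.  ``params.manual_center``
    (with optional ``manual_radius``) bypasses detection entirely.
    """
    params = params or DiscParams()
    if params.manual_center is not None:
        radius = params.manual_radius or min(img.shape) / 16.0
        return OpticDisc(tuple(params.manual_center), float(radius))

    value = hsv_value_channel(img).values.astype(np.float64)
    thresh = np.percentile(value, params.value_percentile)
    # a flat image has no "bright region": demand real contrast above median
    if thresh - np.median(value) < 10:
        raise DetectionError(
            "no bright optic-disc candidate found; pass manual coordinates "
            "via DiscParams(manual_center=(row, col))"
        )
    labels, n = ndimage.label(value >= thresh)
    if n == 0:
        raise DetectionError(
            "no component above brightness threshold; pass manual coordinates"
        )
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    r, c = ndimage.center_of_mass(labels == best)
    radius = float(np.sqrt(sizes[best - 1] / np.pi))
    return OpticDisc((float(r), float(c)), radius)
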