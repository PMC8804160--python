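"""Per-image-region vascular metrics: density, caliber, and tortuosity.

Density is the vessel-pixel fraction of the ROI.  Caliber is the short side
W of a qualified segment's minimum enclosing rectangle, summarised as mean
and median.  Tortuosity is the mean inter-segment angle theta over qualified
marginal/intermediate segments,

    T = (1/n) * sum_i theta_i            (unweighted)

with four weighted variants, T = sum_i w_i theta_i / sum_i w_i, where w_i is
the rectangle area L_i*W_i (area-weighted, combining length and width
information), L_i (length-weighted, compensating segment-size bias), W_i
(width-weighted, amplifying thick vessels) or 1/W_i (width-inversely-weighted,
revealing thin vessels).  A marginal segment's theta is the acute angle
between its long side and its unique neighbor's; an intermediate segment's
theta is the mean of the acute angles to its two neighbors.  Angles are in
degrees throughout.

Undefined metrics (no qualified segment / no qualifying angle) propagate as
NaN and are excluded from group statistics — never coerced to 0, because 0
is a valid tortuosity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import InvalidSpecError
from .extract import OpticDisc, VesselMap, detect_optic_disc, extract_vessels
from .io import FundusImage, RoiMask
from .segments import SegmentGraph, _acute_between, partition_segments, qualify_segments

TORTUOSITY_SCHEMES = ("unweighted", "area", "length", "width", "width_inv")


@dataclass
class InterSegmentAngleSet:
    """Mapping segment_id -> inter-segment angle theta (degrees, [0, 90]).

    Only tortuosity-qualified marginal/intermediate segments appear.
    """

    angles: dict[int, float]

    def __post_init__(self) -> None:
        for sid, theta in self.angles.items():
            if not (0.0 <= theta <= 90.0 + 1e-9):
                raise InvalidSpecError(f"angle {theta} of segment {sid} not in [0, 90]")

    def __len__(self) -> int:
        return len(self.angles)


@dataclass
class VascularMetrics:
    """One image-region's metric vector (NaN marks an undefined metric)."""

    image_id: str
    group: str
    region: str  # HC-cover | RRD | non-RRD
    density: float
    caliber_avg: float
    caliber_median: float
    tort_unweighted: float
    tort_area: float
    tort_length: float
    tort_width: float
    tort_width_inv: float


def absolute_density(vmap: VesselMap, roi: RoiMask) -> float:
    """Vessel-pixel count divided by ROI pixel count (exact integer ratio)."""
    if roi.area == 0:
        raise InvalidSpecError("density undefined on an empty ROI")
    inside = int((vmap.mask & roi.mask).sum())
    if inside != vmap.n_foreground:
        raise InvalidSpecError("vessel map extends outside the ROI")
    return inside / roi.area


def caliber_stats(graph: SegmentGraph) -> tuple[float, float]:
    """(mean, median) rectangle width over caliber-qualified segments.

    Returns (nan, nan) when no segment qualifies: the metric is undefined,
    not zero.
    """
    widths = [s.rect.width for s in graph.segments.values() if s.caliber_ok]
    if not widths:
        return (math.nan, math.nan)
    return float(np.mean(widths)), float(np.median(widths))


def inter_segment_angles(graph: SegmentGraph) -> InterSegmentAngleSet:
    """Inter-segment angle of every tortuosity-qualified segment.

    Marginal (type II): acute angle to the unique neighbor's long side.
    Intermediate (type III): mean of the acute angles to both neighbors.
    """
    out: dict[int, float] = {}
    for sid, seg in graph.segments.items():
        if not seg.tortuosity_ok or seg.seg_type not in ("II", "III"):
            continue
        thetas = [
            _acute_between(seg.rect.angle, graph.segments[n].rect.angle)
            for n in seg.neighbors
        ]
        out[sid] = float(np.mean(thetas))
    return InterSegmentAngleSet(out)


def tortuosity(
    angles: InterSegmentAngleSet,
    graph: SegmentGraph,
    scheme: str = "unweighted",
) -> float:
    """Weighted mean inter-segment angle under one weighting scheme.

    Returns NaN when no angle qualifies.
    """
    if scheme not in TORTUOSITY_SCHEMES:
        raise InvalidSpecError(f"unknown tortuosity scheme {scheme!r}")
    if len(angles) == 0:
        return math.nan
    theta = np.array([angles.angles[sid] for sid in angles.angles])
    if scheme == "unweighted":
        w = np.ones_like(theta)
    else:
        rects = [graph.segments[sid].rect for sid in angles.angles]
        L = np.array([r.length for r in rects])
        W = np.array([r.width for r in rects])
        w = {"area": L * W, "length": L, "width": W, "width_inv": 1.0 / W}[scheme]
    return float(np.sum(w * theta) / np.sum(w))


def compute_all_metrics(
    img: FundusImage,
    roi: RoiMask,
    disc: OpticDisc | None = None,
    config: PipelineConfig | None = None,
    *,
    region: str = "HC-cover",
) -> VascularMetrics:
    """Run extraction -> segmentation -> qualification -> all three metric
    families for one image-region.  Deterministic for fixed inputs/config."""
    config = config or PipelineConfig()
    if disc is None:
        disc = detect_optic_disc(img, config.disc)
    try:
        vmap = extract_vessels(img, roi, config.extract, disc=disc)
    except InvalidSpecError as exc:
        raise InvalidSpecError(f"extraction stage failed: {exc}") from exc
    density = absolute_density(vmap, roi)
    if vmap.n_foreground == 0:
        nan = math.nan
        return VascularMetrics(img.image_id, img.group, region, density,
                               nan, nan, nan, nan, nan, nan, nan)
    try:
        graph = partition_segments(vmap, config.segment, disc=disc)
        qualify_segments(graph, config.qualify)
    except InvalidSpecError as exc:
        raise InvalidSpecError(f"segmentation stage failed: {exc}") from exc
    cal_avg, cal_med = caliber_stats(graph)
    angles = inter_segment_angles(graph)
    torts = [tortuosity(angles, graph, s) for s in TORTUOSITY_SCHEMES]
    return VascularMetrics(img.image_id, img.group, region, density,
                           cal_avg, cal_med, *torts)
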