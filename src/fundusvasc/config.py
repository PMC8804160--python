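"""Tunable parameters of the extraction/segmentation/qualification stages.

Every threshold the pipeline uses lives in one of these dataclasses so that a
run is fully described by (input images, PipelineConfig, seed).  Defaults are
scale-relative where possible so behaviour is stable across frame sizes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class ExtractParams:
    """Vessel-extraction thresholds.

    local_window_frac
        Side of the background-flattening local-average window as a fraction
        of min(rows, cols).
    hysteresis_low_pct, hysteresis_high_pct
        Percentiles of the gradient magnitude inside the ROI used as the
        low/high hysteresis thresholds.
    close_radius
        Disk radius (px) of the morphological closing that merges the paired
        edges of a vessel before hole filling.
    min_component_px
        Connected components smaller than this are dropped as noise.
    """

    local_window_frac: float = 1.0 / 8.0
    hysteresis_low_pct: float = 80.0
    hysteresis_high_pct: float = 93.0
    close_radius: int = 2
    min_component_px: int = 64


@dataclass
class DiscParams:
    """Optic-disc detection: brightness percentile and manual override."""

    value_percentile: float = 99.5
    manual_center: tuple[float, float] | None = None
    manual_radius: float | None = None


@dataclass
class SegmentParams:
    """max_seg_len: longest skeleton run (px) forming one vascular segment."""

    max_seg_len: int = 30


@dataclass
class QualifyParams:
    """Segment qualification criteria.

    A segment is caliber-computable iff its rectangle fill ratio, long-side
    length, radial alignment with the optic disc, and distance from the disc
    centre all pass.  Tortuosity-computable additionally requires a marginal
    (type II) or intermediate (type III) segment.
    """

    min_fill: float = 0.5
    min_L: float = 8.0
    max_L: float = 60.0
    max_radial_angle: float = 60.0
    min_disc_dist_factor: float = 1.5


@dataclass
class PipelineConfig:
    cover_fraction: float = 0.43
    extract: ExtractParams = field(default_factory=ExtractParams)
    disc: DiscParams = field(default_factory=DiscParams)
    segment: SegmentParams = field(default_factory=SegmentParams)
    qualify: QualifyParams = field(default_factory=QualifyParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable hex digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
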