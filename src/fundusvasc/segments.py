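"""Vascular segment model: skeleton partitioning, minimum enclosing
rectangles, adjacency, type classification, and qualification criteria.

A vessel map is skeletonized and the skeleton cut at branch points; each
branch-free arc is subdivided into runs of at most ``max_seg_len`` skeleton
pixels.  Consecutive runs of one arc are neighbors; runs meeting at a
bifurcation are not (inter-segment angles are measured along a vessel, never
across branchings).  Segment types: I = isolated (0 neighbors), II =
marginal (1), III = intermediate (2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import atan2, degrees

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import skeletonize

from .config import QualifyParams, SegmentParams
from .errors import InvalidSpecError
from .extract import OpticDisc, VesselMap


@dataclass
class MinRect:
    """Minimum-area enclosing rectangle of a pixel set.

    length is the long side L, width the short side W (both in px, already
    extended by 1 px for pixel extent), angle the orientation of the long
    side versus the column axis in degrees, in [0, 180).
    """

    center: tuple[float, float]
    length: float
    width: float
    angle: float

    @property
    def area(self) -> float:
        return self.length * self.width


@dataclass
class VesselSegment:
    segment_id: int
    pixels: np.ndarray          # (n, 2) int array of (row, col)
    skeleton: np.ndarray        # ordered (m, 2) skeleton polyline
    rect: MinRect
    neighbors: tuple[int, ...] = ()
    caliber_ok: bool = False
    tortuosity_ok: bool = False

    @property
    def seg_type(self) -> str:
        """'I' isolated, 'II' marginal, 'III' intermediate."""
        return {0: "I", 1: "II", 2: "III"}[min(len(self.neighbors), 2)]


@dataclass
class SegmentGraph:
    segments: dict[int, VesselSegment]
    disc: OpticDisc | None = None

    @property
    def n_tortuosity(self) -> int:
        """The count n of qualified marginal + intermediate segments."""
        return sum(
            1 for s in self.segments.values()
            if s.tortuosity_ok and s.seg_type in ("II", "III")
        )


# ---------------------------------------------------------------------------
# minimum enclosing rectangle (rotating calipers)


def _direction_angle(dr: float, dc: float) -> float:
    """Undirected line angle vs the column axis, in [0, 180)."""
    a = degrees(atan2(dr, dc)) % 180.0
    return 0.0 if a >= 180.0 - 1e-9 else a


def min_enclosing_rectangle(pixels: np.ndarray) -> MinRect:
    """Minimum-area rectangle (any orientation) enclosing pixel centers.

    Rotating calipers over the convex hull: the optimal rectangle has a side
    collinear with a hull edge, so scanning hull-edge directions is exact.
    Both sides are extended by 1 px to account for the unit pixel extent;
    degenerate sets (single pixel, collinear points) are handled directly.
    """
    pts = np.atleast_2d(np.asarray(pixels, dtype=np.float64))
    if pts.shape[0] == 0:
        raise InvalidSpecError("cannot fit a rectangle to zero pixels")
    pts = np.unique(pts, axis=0)
    if pts.shape[0] == 1:
        return MinRect((float(pts[0, 0]), float(pts[0, 1])), 1.0, 1.0, 0.0)

    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError:  # collinear points
        span = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(span, full_matrices=False)
        axis = vt[0]
        proj = span @ axis
        length = proj.max() - proj.min()
        mid = pts.mean(axis=0) + axis * (proj.max() + proj.min()) / 2.0
        return MinRect(
            (float(mid[0]), float(mid[1])),
            float(length) + 1.0, 1.0,
            _direction_angle(axis[0], axis[1]),
        )

    best = None
    edges = np.diff(np.vstack([hp, hp[:1]]), axis=0)
    for edge in edges:
        norm = np.hypot(edge[0], edge[1])
        if norm < 1e-12:
            continue
        u = edge / norm
        v = np.array([-u[1], u[0]])
        pu = hp @ u
        pv = hp @ v
        ext_u = pu.max() - pu.min()
        ext_v = pv.max() - pv.min()
        area = ext_u * ext_v  # hull area is the calipers objective
        if best is None or area < best[0] - 1e-12:
            cen = (u * (pu.max() + pu.min()) + v * (pv.max() + pv.min())) / 2.0
            best = (area, ext_u, ext_v, u, v, cen)

    _, ext_u, ext_v, u, v, cen = best
    if ext_u >= ext_v:
        length, width, axis = ext_u + 1.0, ext_v + 1.0, u
    else:
        length, width, axis = ext_v + 1.0, ext_u + 1.0, v
    return MinRect(
        (float(cen[0]), float(cen[1])),
        float(length), float(width),
        _direction_angle(axis[0], axis[1]),
    )


# ---------------------------------------------------------------------------
# skeleton partitioning


_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _order_arc(coords: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order the pixels of a branch-free arc by walking it end to end."""
    deg = {
        p: sum((p[0] + dr, p[1] + dc) in coords for dr, dc in _NEIGH)
        for p in coords
    }
    start = min((p for p in coords if deg[p] <= 1), default=min(coords))
    ordered = [start]
    seen = {start}
    cur = start
    while True:
        # prefer 4-adjacent continuation for a consistent walk on staircases
        nxt = None
        for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0),
                       (-1, -1), (-1, 1), (1, -1), (1, 1)):
            cand = (cur[0] + dr, cur[1] + dc)
            if cand in coords and cand not in seen:
                nxt = cand
                break
        if nxt is None:
            break
        ordered.append(nxt)
        seen.add(nxt)
        cur = nxt
    # stray pixels (rare, non-simple arcs) are appended; they still belong
    for p in coords - seen:
        ordered.append(p)
    return ordered


def partition_segments(
    vmap: VesselMap,
    max_seg_len: int | SegmentParams | None = None,
    disc: OpticDisc | None = None,
) -> SegmentGraph:
    """Partition a binary vessel map into vascular segments.

    Every foreground pixel is assigned to the segment of its nearest
    skeleton-run pixel, so segment pixel sets partition the map exactly.
    """
    if isinstance(max_seg_len, SegmentParams):
        max_seg_len = max_seg_len.max_seg_len
    max_seg_len = max_seg_len or SegmentParams().max_seg_len
    if vmap.n_foreground == 0:
        raise InvalidSpecError("cannot partition an empty vessel map")

    skel = skeletonize(vmap.mask)
    nbr_count = ndimage.convolve(
        skel.astype(np.uint8), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]),
        mode="constant",
    )
    branch = skel & (nbr_count >= 3)
    arcs_mask = skel & ~branch
    if not arcs_mask.any():
        # tiny blob whose skeleton is all branch pixels: treat it whole
        arcs_mask = skel
    labels, n_arcs = ndimage.label(arcs_mask, structure=np.ones((3, 3)))

    run_of_site = np.full(labels.shape, -1, dtype=np.int32)
    runs: list[np.ndarray] = []
    run_neighbors: dict[int, set[int]] = {}
    for arc_id in range(1, n_arcs + 1):
        coords = set(map(tuple, np.argwhere(labels == arc_id)))
        ordered = _order_arc(coords)
        n = len(ordered)
        k = max(1, int(np.ceil(n / max_seg_len)))
        chunks = np.array_split(np.array(ordered, dtype=np.int64), k)
        first = len(runs)
        for j, chunk in enumerate(chunks):
            rid = first + j
            runs.append(chunk)
            run_neighbors[rid] = set()
            run_of_site[chunk[:, 0], chunk[:, 1]] = rid
            if j > 0:  # consecutive runs of one arc are neighbors
                run_neighbors[rid].add(rid - 1)
                run_neighbors[rid - 1].add(rid)

    # nearest-site assignment of every foreground pixel
    sites = run_of_site >= 0
    _, (ir, ic) = ndimage.distance_transform_edt(~sites, return_indices=True)
    assign = run_of_site[ir, ic]

    segments: dict[int, VesselSegment] = {}
    fg = np.argwhere(vmap.mask)
    seg_labels = assign[fg[:, 0], fg[:, 1]]
    order = np.argsort(seg_labels, kind="stable")
    fg, seg_labels = fg[order], seg_labels[order]
    bounds = np.searchsorted(seg_labels, np.arange(len(runs) + 1))
    for rid in range(len(runs)):
        px = fg[bounds[rid]:bounds[rid + 1]]
        if len(px) == 0:
            continue
        segments[rid] = VesselSegment(
            segment_id=rid,
            pixels=px,
            skeleton=runs[rid],
            rect=min_enclosing_rectangle(px),
        )
    # restrict adjacency to surviving segments
    for rid, seg in segments.items():
        seg.neighbors = tuple(sorted(n for n in run_neighbors[rid] if n in segments))
    return SegmentGraph(segments, disc=disc)


# ---------------------------------------------------------------------------
# qualification


def _acute_between(a: float, b: float) -> float:
    """Acute angle (degrees, [0, 90]) between two undirected line angles."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def qualify_segments(
    graph: SegmentGraph,
    criteria: QualifyParams | None = None,
    disc: OpticDisc | None = None,
) -> SegmentGraph:
    """Set caliber_ok / tortuosity_ok flags on every segment, in place.

    caliber_ok requires: rectangle fill ratio >= min_fill; min_L <= L <=
    max_L; the acute angle between the rectangle's long side and the ray
    from the optic-disc center through the rectangle center <= max_radial_angle
    (retinal vessels run roughly radially); and distance from the disc center
    >= min_disc_dist_factor x disc radius.  tortuosity_ok adds the
    requirement of a marginal or intermediate segment type.
    """
    criteria = criteria or QualifyParams()
    disc = disc or graph.disc
    if disc is None:
        raise InvalidSpecError("qualification requires the optic disc")
    graph.disc = disc
    min_dist = criteria.min_disc_dist_factor * disc.radius
    for seg in graph.segments.values():
        rect = seg.rect
        fill = len(seg.pixels) / rect.area
        dr = rect.center[0] - disc.center[0]
        dc = rect.center[1] - disc.center[1]
        dist = float(np.hypot(dr, dc))
        if dist > 1e-9:
            radial = _acute_between(rect.angle, _direction_angle(dr, dc))
        else:
            radial = 0.0
        ok = (
            fill >= criteria.min_fill
            and criteria.min_L <= rect.length <= criteria.max_L
            and radial <= criteria.max_radial_angle
            and dist >= min_dist
        )
        seg.caliber_ok = ok
        seg.tortuosity_ok = ok and seg.seg_type in ("II", "III")
    return graph
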