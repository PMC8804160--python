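"""Synthetic fundus cohort generator with known vessel ground truth.

Real ultra-widefield captures show dark vessel trees sprouting from a bright
optic disc toward the periphery on a brighter, vignetted background.  This
module grows procedural vessel trees (a random walk with bounded turning
angle, binary branching and width tapering), renders them into fundus-like
RGB frames, fabricates detached/attached region partitions, and assembles
two-group cohorts whose generating parameters differ by known multipliers —
so every downstream stage can be tested against analytic truth.

All outputs are pure functions of the seed and the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, cos, pi, radians, sin

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidSpecError
from .io import FundusImage, RoiMask, RoiPartition, make_general_cover

# ---------------------------------------------------------------------------
# truth containers


@dataclass
class VesselTreeTruth:
    """Ground-truth geometry of one synthetic vascular tree.

    centerlines: list of (n_i, 2) float arrays of (row, col) points.
    widths: per-polyline width profiles, arrays aligned with centerlines.
    bend_amplitudes: per-polyline bound (degrees) on the per-step heading
    change used to grow it.
    parents: index of each polyline's parent (-1 for roots).
    """

    centerlines: list[np.ndarray]
    widths: list[np.ndarray]
    bend_amplitudes: list[float]
    parents: list[int]
    disc_center: tuple[float, float]
    disc_radius: float
    image_size: tuple[int, int]


@dataclass
class CohortSpec:
    """Design of a two-group synthetic cohort (group A = HC, group B = RRD).

    The multipliers scale group B's generating parameters relative to A's:
    density via the root count, caliber via the root width, tortuosity via
    the bend amplitude.
    """

    n_per_group: int
    density_mult: float = 1.0
    caliber_mult: float = 1.0
    tortuosity_mult: float = 1.0
    detachment_fraction: float = 0.4
    image_size: tuple[int, int] = (256, 256)
    seed: int = 0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise InvalidSpecError("n_per_group must be >= 1")
        if min(self.density_mult, self.caliber_mult, self.tortuosity_mult) <= 0:
            raise InvalidSpecError("effect multipliers must be > 0")
        if not (0.0 <= self.detachment_fraction <= 1.0):
            raise InvalidSpecError("detachment_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# tree growth


def grow_vessel_tree(
    seed: int,
    n_roots: int = 6,
    bend_amplitude: float = 20.0,
    width_root: float = 5.0,
    image_size: tuple[int, int] = (512, 512),
    *,
    step: float = 2.0,
    branch_prob: float = 0.012,
    taper: float = 0.72,
    max_depth: int = 2,
) -> VesselTreeTruth:
    """Grow a branching vessel tree radiating from the optic-disc rim.

    Each polyline is a bounded-turning random walk: the heading changes by
    Uniform(-bend_amplitude, +bend_amplitude) degrees per step, so a zero
    amplitude yields straight rays.  Branches sprout with probability
    ``branch_prob`` per step, start on the parent centerline, and taper to
    ``taper`` times the parent width (never below 1 px).  Deterministic for a
    fixed seed.
    """
    if n_roots < 1:
        raise InvalidSpecError("n_roots must be >= 1")
    if bend_amplitude < 0:
        raise InvalidSpecError("bend_amplitude must be >= 0")
    if width_root < 1:
        raise InvalidSpecError("width_root must be >= 1 px")
    rows, cols = image_size
    # keep the disc under ~0.35% of the frame, as in real widefield captures
    disc_radius = min(rows, cols) / 30.0
    if min(rows, cols) < 60:  # disc (plus margin) must fit in the frame
        raise InvalidSpecError(f"image {image_size} too small to contain the disc")
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)

    rng = np.random.default_rng(seed)
    margin = 2.0
    centerlines: list[np.ndarray] = []
    widths: list[np.ndarray] = []
    bends: list[float] = []
    parents: list[int] = []

    # (start point, heading deg, width, depth, parent polyline index)
    queue: list[tuple[np.ndarray, float, float, int, int]] = []
    base = rng.uniform(0, 360)
    for k in range(n_roots):
        ang = base + 360.0 * k / n_roots + rng.uniform(-10, 10)
        start = np.array(
            [center[0] + disc_radius * sin(radians(ang)),
             center[1] + disc_radius * cos(radians(ang))]
        )
        queue.append((start, ang, float(width_root), 0, -1))

    while queue:
        pos, heading, width, depth, parent = queue.pop(0)
        my_index = len(centerlines)
        n_children = 0
        pts = [pos.copy()]
        for _ in range(10000):
            if bend_amplitude > 0:
                heading += rng.uniform(-bend_amplitude, bend_amplitude)
            nxt = pts[-1] + step * np.array(
                [sin(radians(heading)), cos(radians(heading))]
            )
            if not (margin <= nxt[0] <= rows - 1 - margin
                    and margin <= nxt[1] <= cols - 1 - margin):
                break
            pts.append(nxt)
            if (depth < max_depth and n_children < 2 and len(pts) > 5
                    and rng.random() < branch_prob):  # binary branching
                side = 1.0 if rng.random() < 0.5 else -1.0
                child_heading = heading + side * rng.uniform(25, 50)
                child_width = max(1.0, width * taper)
                queue.append((pts[-1].copy(), child_heading, child_width,
                              depth + 1, my_index))
                n_children += 1
        if len(pts) < 2:  # root started too close to the border
            # drop any children queued from it is impossible (none were);
            # keep topology consistent by skipping the polyline entirely
            queue = [q for q in queue if q[4] != my_index]
            continue
        poly = np.array(pts)
        centerlines.append(poly)
        widths.append(np.full(len(poly), width))
        bends.append(float(bend_amplitude))
        parents.append(parent)

    return VesselTreeTruth(centerlines, widths, bends, parents,
                           center, disc_radius, (rows, cols))


# ---------------------------------------------------------------------------
# rendering


def rasterize_tree(truth: VesselTreeTruth) -> np.ndarray:
    """Boolean vessel mask: pixel centers within half-width of a centerline."""
    rows, cols = truth.image_size
    mask = np.zeros((rows, cols), dtype=bool)
    for poly, wprof in zip(truth.centerlines, truth.widths):
        radius = (float(wprof.max()) - 1.0) / 2.0
        # densify the polyline so disk stamping leaves no gaps
        seg = np.diff(poly, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        samples = [poly[0]]
        for p0, d, ln in zip(poly[:-1], seg, seglen):
            n = max(1, int(ceil(ln / 0.3)))
            t = np.arange(1, n + 1)[:, None] / n
            samples.append(p0 + t * d)
        pts = np.vstack(samples)
        r_lo = max(0, int(np.floor(pts[:, 0].min() - radius - 1)))
        r_hi = min(rows, int(np.ceil(pts[:, 0].max() + radius + 2)))
        c_lo = max(0, int(np.floor(pts[:, 1].min() - radius - 1)))
        c_hi = min(cols, int(np.ceil(pts[:, 1].max() + radius + 2)))
        if r_hi <= r_lo or c_hi <= c_lo:
            continue
        rr = np.arange(r_lo, r_hi)[:, None]
        cc = np.arange(c_lo, c_hi)[None, :]
        local = np.zeros((r_hi - r_lo, c_hi - c_lo), dtype=bool)
        # chunk the sample points to bound memory
        for start in range(0, len(pts), 256):
            chunk = pts[start:start + 256]
            d2 = ((rr[..., None] - chunk[:, 0]) ** 2
                  + (cc[..., None] - chunk[:, 1]) ** 2)
            local |= (d2.min(axis=2) <= (radius + 1e-9) ** 2)
        mask[r_lo:r_hi, c_lo:c_hi] |= local
    return mask


def render_fundus(
    truth: VesselTreeTruth,
    noise_sd: float = 5.0,
    *,
    image_id: str = "synthetic",
    group: str = "HC",
    rng: np.random.Generator | None = None,
) -> tuple[FundusImage, "np.ndarray"]:
    """Render a truth tree into a fundus-like RGB frame.

    Background: radial brightness falloff; vessels darker than background in
    the green channel; the optic disc is the brightest region.  Returns the
    image and the boolean ground-truth vessel map.
    """
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")
    rng = rng or np.random.default_rng(0)
    rows, cols = truth.image_size
    cr, cc0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    d = np.hypot(rr - cr, cc - cc0) / np.hypot(cr, cc0)
    background = 190.0 - 60.0 * d ** 2

    vmask = rasterize_tree(truth)
    green = np.where(vmask, background * 0.40, background)
    red = np.where(vmask, background * 0.75, background * 1.05)
    blue = np.where(vmask, background * 0.30, background * 0.55)

    disc = (np.hypot(rr - truth.disc_center[0], cc - truth.disc_center[1])
            <= truth.disc_radius)
    green = np.where(disc, 245.0, green)
    red = np.where(disc, 250.0, red)
    blue = np.where(disc, 230.0, blue)

    img = np.stack([red, green, blue], axis=-1)
    img = ndimage.gaussian_filter(img, sigma=(0.8, 0.8, 0))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return FundusImage(img, image_id=image_id, group=group), vmask


# ---------------------------------------------------------------------------
# region partitions


def make_detachment_partition(
    image_size: tuple[int, int],
    fraction: float,
    seed: int = 0,
    *,
    cover: RoiMask | None = None,
    strict_positive: bool = False,
) -> RoiPartition:
    """Split the general cover into a detached (RRD) and attached region.

    The detached region is the side of a random chord of the oval chosen so
    its area is ``fraction`` of the cover; both regions are simply connected
    (a half-plane cut of a convex oval).
    """
    if not (0.0 <= fraction <= 1.0):
        raise InvalidSpecError("fraction must lie in [0, 1]")
    cover = cover or make_general_cover(*image_size)
    cov = cover.mask
    if strict_positive and (fraction <= 0.0 or fraction >= 1.0
                            or round(fraction * cov.sum()) < 1
                            or round((1 - fraction) * cov.sum()) < 1):
        raise InvalidSpecError(
            f"fraction {fraction} leaves an empty region on this cover"
        )
    rows, cols = cov.shape
    if fraction == 0.0:
        return RoiPartition(RoiMask(np.zeros_like(cov)), RoiMask(cov.copy()))
    if fraction == 1.0:
        return RoiPartition(RoiMask(cov.copy()), RoiMask(np.zeros_like(cov)))
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, pi)
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    proj = (rr - (rows - 1) / 2.0) * sin(theta) + (cc - (cols - 1) / 2.0) * cos(theta)
    cut = np.quantile(proj[cov], fraction)
    rrd = cov & (proj <= cut)
    return RoiPartition(RoiMask(rrd), RoiMask(cov & ~rrd))


# ---------------------------------------------------------------------------
# cohorts


#: baseline generating parameters of a healthy synthetic eye
BASE_N_ROOTS = 6.0
BASE_WIDTH = 5.0
BASE_BEND = 20.0


def draw_cohort_params(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-image generating parameters for both groups.

    Between-eye variability is lognormal around the group mean; group B's
    means are group A's times the spec multipliers.  Returns one row per
    image: image_id, group, region, gen_density, gen_width,
    gen_bend_amplitude, seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, label, region, (md, mw, mb) in (
        ("A", "HC", "HC-cover", (1.0, 1.0, 1.0)),
        ("B", "RRD", "RRD",
         (spec.density_mult, spec.caliber_mult, spec.tortuosity_mult)),
    ):
        for i in range(spec.n_per_group):
            rows.append(
                {
                    "image_id": f"{label.lower()}_{i:03d}",
                    "group": label,
                    "region": region,
                    "gen_density": BASE_N_ROOTS * md * np.exp(rng.normal(0, 0.10)),
                    "gen_width": BASE_WIDTH * mw * np.exp(rng.normal(0, 0.06)),
                    "gen_bend_amplitude": BASE_BEND * mb * np.exp(rng.normal(0, 0.10)),
                    "seed": int(rng.integers(0, 2**31 - 1)),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[FundusImage], dict[str, RoiPartition | None], pd.DataFrame]:
    """Generate a full two-group cohort: images, partitions, truth table.

    HC images carry no partition (None: they are analysed under the general
    cover); RRD images carry a detachment partition of the stated fraction.
    Fully reproducible from ``spec.seed``.
    """
    params = draw_cohort_params(spec)
    images: list[FundusImage] = []
    partitions: dict[str, RoiPartition | None] = {}
    cover = make_general_cover(*spec.image_size)
    for rec in params.itertuples(index=False):
        img_seed = int(rec.seed)
        truth = grow_vessel_tree(
            img_seed,
            n_roots=max(1, round(rec.gen_density)),
            bend_amplitude=rec.gen_bend_amplitude,
            width_root=max(1.0, rec.gen_width),
            image_size=spec.image_size,
        )
        img, _ = render_fundus(
            truth,
            spec.noise_sd,
            image_id=rec.image_id,
            group=rec.group,
            rng=np.random.default_rng(img_seed + 1),
        )
        images.append(img)
        if rec.group == "RRD":
            partitions[rec.image_id] = make_detachment_partition(
                spec.image_size, spec.detachment_fraction, seed=img_seed + 2,
                cover=cover,
            )
        else:
            partitions[rec.image_id] = None
    return images, partitions, params
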