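"""Image and table I/O, the general oval cover, and region partitions.

Coordinate convention (used package-wide): (row, col), 0-based, pixel centers
at integer coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import pi, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, InvalidSpecError

#: fixed column order of the per-image metrics table
METRICS_COLUMNS = (
    "image_id",
    "group",
    "region",
    "density",
    "caliber_avg",
    "caliber_median",
    "tort_unweighted",
    "tort_area",
    "tort_length",
    "tort_width",
    "tort_width_inv",
)

#: the eight vascular metrics compared between groups
METRIC_NAMES = METRICS_COLUMNS[3:]


@dataclass
class FundusImage:
    """An RGB fundus photograph plus its cohort labels.

    pixels is rows x cols x 3, uint8.  group is "HC" or "RRD".
    """

    pixels: np.ndarray
    image_id: str = ""
    group: str = "HC"
    source_path: str | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise FormatError(
                f"fundus image must be rows x cols x 3, got shape {p.shape}"
            )
        self.pixels = p.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class RoiMask:
    """Boolean inclusion grid; `area` is the included-pixel count."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError("ROI mask must be 2-D")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class RoiPartition:
    """Disjoint split of the general cover into detached (RRD) and attached
    (non-RRD) regions."""

    rrd_mask: RoiMask
    non_rrd_mask: RoiMask

    def __post_init__(self) -> None:
        if self.rrd_mask.shape != self.non_rrd_mask.shape:
            raise FormatError("partition masks must share a shape")
        if np.any(self.rrd_mask.mask & self.non_rrd_mask.mask):
            raise InvalidSpecError("partition masks overlap")


def read_image(path: str | Path, image_id: str | None = None, group: str = "HC") -> FundusImage:
    """Read a PNG/TIFF/JPEG fundus image as 8-bit RGB.

    Grayscale inputs are replicated to three channels; 16-bit inputs are
    rescaled to 8-bit.  Unreadable files raise IOError naming the path.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # truncated / undecodable
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise FormatError(f"zero-size image: {path}")
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[2] > 3:  # drop alpha
        arr = arr[:, :, :3]
    return FundusImage(arr, image_id=image_id or path.stem, group=group,
                       source_path=str(path))


def make_general_cover(rows: int, cols: int, area_fraction: float = 0.43) -> RoiMask:
    """Centered axis-aligned oval cover occupying `area_fraction` of the frame.

    The ellipse keeps the frame's aspect ratio (semi-axes proportional to rows
    and cols) and is scaled so that the included-pixel fraction matches the
    request; a pixel is included iff its center satisfies the ellipse
    inequality.  The largest such inscribed ellipse has area fraction pi/4.
    """
    if not (0.0 < area_fraction <= pi / 4 + 1e-12):
        raise InvalidSpecError(
            f"area_fraction must lie in (0, pi/4], got {area_fraction}"
        )
    # continuous area: pi * a * b = f * rows * cols with a = alpha*rows/2
    alpha = sqrt(4.0 * area_fraction / pi)
    a = alpha * rows / 2.0
    b = alpha * cols / 2.0
    cr = (rows - 1) / 2.0
    cc = (cols - 1) / 2.0
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    mask = ((r - cr) / a) ** 2 + ((c - cc) / b) ** 2 <= 1.0
    return RoiMask(mask)


def load_region_cover(cover_image_path: str | Path, general_cover: RoiMask) -> RoiPartition:
    """Read a doctor-drawn region cover and split the general cover.

    Dialect: nonzero pixels mark the detached (RRD) region as a filled mask
    (use :func:`fill_boundary` first if the file encodes only a closed
    boundary curve).  Both returned masks are intersected with the general
    cover; together they partition it.
    """
    path = Path(cover_image_path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except Exception as exc:
        raise IOError(f"cannot read cover image {path}: {exc}") from exc
    if arr.shape != general_cover.shape:
        raise FormatError(
            f"cover {path} has shape {arr.shape}, expected {general_cover.shape}"
        )
    nz = arr > 0
    rrd = nz & general_cover.mask
    if not rrd.any():
        warnings.warn(f"cover {path} marks no RRD pixels inside the general cover")
    return RoiPartition(RoiMask(rrd), RoiMask(general_cover.mask & ~rrd))


def fill_boundary(boundary: np.ndarray) -> np.ndarray:
    """Flood-fill a closed boundary curve into a filled region mask."""
    from scipy.ndimage import binary_fill_holes

    return binary_fill_holes(np.asarray(boundary, dtype=bool))


def write_mask(mask: RoiMask, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG with values 0/255."""
    Image.fromarray(np.where(mask.mask, 255, 0).astype(np.uint8)).save(path)


def write_image(img: FundusImage, path: str | Path) -> None:
    Image.fromarray(img.pixels).save(path)


def write_metrics_table(rows, path: str | Path) -> None:
    """Write per-image-region VascularMetrics rows as CSV.

    Values round-trip through read_metrics_table to within 1e-9 (floats are
    written at full repr precision).  An empty row list is an error and no
    file is created.
    """
    rows = list(rows)
    if not rows:
        raise InvalidSpecError("refusing to write an empty metrics table")
    records = []
    for row in rows:
        records.append({col: getattr(row, col) for col in METRICS_COLUMNS})
    df = pd.DataFrame.from_records(records, columns=list(METRICS_COLUMNS))
    df.to_csv(path, index=False)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metrics table {path} lacks columns {sorted(missing)}")
    return df
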