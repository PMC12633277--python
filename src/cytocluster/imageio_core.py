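"""Record/mask/label data model and file I/O.

Coordinate conventions used everywhere downstream:

* pixel grids are row-major, origin top-left, 0-based indices;
* polygon vertices are ``(x, y)`` pairs normalized to ``[0, 1]`` with
  ``x = column / width`` and ``y = row / height``;
* a pixel ``(r, c)`` occupies the unit square ``[c, c+1] x [r, r+1]`` in
  continuous coordinates, so a full-frame mask maps to the unit square.

Supported file formats: 8-bit PNG and TIFF images, single-plane ``{0, 255}``
PNG masks, plain-text polygon label files (one ``class_id x1 y1 x2 y2 ...``
line per instance, 6-decimal fixed precision), and CSV dataset manifests
with columns ``record_id, brightfield, cd61, cd45, class, phenotype``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient
from shapely.ops import unary_union
from skimage.measure import label as cc_label

from cytocluster.errors import (
    EmptyRegionError,
    FormatError,
    InputError,
    RegistrationError,
)

__all__ = [
    "ChannelImage",
    "BinaryMask",
    "PolygonLabel",
    "ClusterClass",
    "PhenotypeLabel",
    "MultiChannelRecord",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_record",
    "mask_to_polygon_label",
    "polygon_to_mask",
    "write_polygon_labels",
    "read_polygon_labels",
    "read_manifest",
    "write_manifest",
]


class ClusterClass(enum.Enum):
    """Stage-1 decision: does the frame show an aggregated cell cluster?"""

    CLUSTER = "cluster"
    NON_CLUSTER = "non_cluster"


class PhenotypeLabel(enum.Enum):
    """Stage-2 decision for frames that contain a cluster."""

    RBC_CLUSTER = "rbc_cluster"
    PLATELET_CLUSTER = "platelet_cluster"
    WBC_CLUSTER = "wbc_cluster"
    WBC_PLATELET_CLUSTER = "wbc_platelet_cluster"
    EXCLUDED_ARTIFACT = "excluded_artifact"


@dataclass(frozen=True)
class ChannelImage:
    """A single 8-bit channel image: 2-D grayscale or H x W x 3 RGB."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3 and px.shape[2] != 3:
            raise FormatError(
                f"RGB image must have 3 planes, got shape {px.shape}"
            )
        if px.ndim not in (2, 3):
            raise FormatError(f"image must be 2-D or 3-plane, got ndim={px.ndim}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"image must be at least 1x1, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FormatError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    def to_rgb(self) -> "ChannelImage":
        """Promote grayscale to RGB by plane replication (no-op on RGB)."""
        if self.is_rgb:
            return self
        return ChannelImage(np.repeat(self.pixels[:, :, None], 3, axis=2))


@dataclass(frozen=True)
class BinaryMask:
    """Pixel-aligned boolean region (cluster contour fill or stain region)."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise FormatError(f"mask must be 2-D, got ndim={g.ndim}")
        object.__setattr__(self, "grid", g.astype(bool))

    @property
    def height(self) -> int:
        return int(self.grid.shape[0])

    @property
    def width(self) -> int:
        return int(self.grid.shape[1])

    @property
    def area(self) -> int:
        """Count of true pixels."""
        return int(self.grid.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_shape(self, other)
        return BinaryMask(self.grid & other.grid)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_shape(self, other)
        return BinaryMask(self.grid | other.grid)


def _check_same_shape(a: BinaryMask, b: BinaryMask) -> None:
    if a.grid.shape != b.grid.shape:
        raise RegistrationError(
            f"mask shapes differ: {a.grid.shape} vs {b.grid.shape}"
        )


@dataclass(frozen=True)
class PolygonLabel:
    """One instance contour: class id + normalized (x, y) vertex ring."""

    class_id: int
    vertices: np.ndarray  # (n, 2) float, each coordinate in [0, 1]

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise FormatError("class_id must be non-negative")
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise FormatError(
                f"polygon needs >= 3 (x, y) vertices, got array of shape {v.shape}"
            )
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise FormatError("polygon coordinates must be normalized to [0, 1]")
        object.__setattr__(self, "vertices", np.clip(v, 0.0, 1.0))


@dataclass
class MultiChannelRecord:
    """One co-registered brightfield + CD61 + CD45 triplet with optional truth.

    All three channels must share the same height and width; a truth mask,
    when present, shares that shape too.
    """

    record_id: str
    brightfield: ChannelImage
    cd61: ChannelImage
    cd45: ChannelImage
    truth_mask: Optional[BinaryMask] = None
    truth_class: Optional[ClusterClass] = None
    truth_phenotype: Optional[PhenotypeLabel] = None

    def __post_init__(self) -> None:
        ref = (self.brightfield.height, self.brightfield.width)
        for name in ("cd61", "cd45"):
            ch: ChannelImage = getattr(self, name)
            if (ch.height, ch.width) != ref:
                raise RegistrationError(
                    f"channel '{name}' has shape {(ch.height, ch.width)}, "
                    f"brightfield has {ref}"
                )
        if self.truth_mask is not None and (
            self.truth_mask.height,
            self.truth_mask.width,
        ) != ref:
            raise RegistrationError(
                f"truth_mask shape {(self.truth_mask.height, self.truth_mask.width)} "
                f"does not match channels {ref}"
            )

    @property
    def height(self) -> int:
        return self.brightfield.height

    @property
    def width(self) -> int:
        return self.brightfield.width


# ---------------------------------------------------------------------------
# image / mask files
# ---------------------------------------------------------------------------


def read_image(path: str | Path) -> ChannelImage:
    """Read an 8-bit PNG or TIFF file; alpha planes are dropped."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder failure
        raise InputError(f"cannot decode image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        raise InputError(f"{path}: expected 8-bit image, got dtype {arr.dtype}")
    return ChannelImage(arr)


def write_image(img: ChannelImage, path: str | Path) -> None:
    iio.imwrite(Path(path), img.pixels)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a single-plane {0, 255} PNG mask."""
    img = read_image(path)
    px = img.pixels
    if px.ndim == 3:
        px = px[:, :, 0]
    return BinaryMask(px > 127)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    iio.imwrite(Path(path), np.where(mask.grid, 255, 0).astype(np.uint8))


def read_record(
    brightfield_path: str | Path,
    cd61_path: str | Path,
    cd45_path: str | Path,
    record_id: str | None = None,
) -> MultiChannelRecord:
    """Load one record from three image files.

    The brightfield channel is collapsed to grayscale if stored as RGB with
    identical planes; fluorescence channels are promoted to RGB by plane
    replication when stored grayscale.  Raises :class:`RegistrationError`
    naming the offending channel if shapes disagree.
    """
    bf = read_image(brightfield_path)
    if bf.is_rgb:
        bf = ChannelImage(bf.pixels[:, :, 0])
    cd61 = read_image(cd61_path).to_rgb()
    cd45 = read_image(cd45_path).to_rgb()
    ref = (bf.height, bf.width)
    for name, ch in (("cd61", cd61), ("cd45", cd45)):
        if (ch.height, ch.width) != ref:
            raise RegistrationError(
                f"channel '{name}' ({ch.height}x{ch.width}) is not co-registered "
                f"with brightfield ({ref[0]}x{ref[1]})"
            )
    rid = record_id if record_id is not None else Path(brightfield_path).stem
    return MultiChannelRecord(record_id=rid, brightfield=bf, cd61=cd61, cd45=cd45)


# ---------------------------------------------------------------------------
# polygon <-> mask
# ---------------------------------------------------------------------------


def _largest_component(grid: np.ndarray) -> np.ndarray:
    """Boolean grid of the largest 4-connected true component."""
    labels = cc_label(grid, connectivity=1)
    if labels.max() == 0:
        return np.zeros_like(grid, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _pixel_union_polygon(grid: np.ndarray) -> Polygon:
    """Exact outer polygon of the union of unit pixel squares (x=col, y=row)."""
    rows, cols = np.nonzero(grid)
    boxes = shapely.box(cols, rows, cols + 1.0, rows + 1.0)
    merged = unary_union(boxes)
    if merged.geom_type == "MultiPolygon":  # cannot happen for 4-connected input
        merged = max(merged.geoms, key=lambda g: g.area)
    # exterior only, collinear vertices removed, CCW orientation
    poly = Polygon(merged.exterior)
    poly = orient(poly.simplify(0), sign=1.0)
    return poly


def mask_to_polygon_label(mask: BinaryMask, class_id: int = 0) -> PolygonLabel:
    """Trace the outer contour of the largest connected region of *mask*.

    Vertices follow pixel-square corners (exact for the rasterization
    convention of :func:`polygon_to_mask`), normalized by width/height,
    oriented counter-clockwise.  Only the largest 4-connected component is
    exported; interior holes are dropped.
    """
    if mask.area == 0:
        raise EmptyRegionError("cannot trace a polygon from an empty mask")
    comp = _largest_component(mask.grid)
    poly = _pixel_union_polygon(comp)
    xy = np.asarray(poly.exterior.coords)[:-1]  # drop closing duplicate
    verts = np.column_stack([xy[:, 0] / mask.width, xy[:, 1] / mask.height])
    return PolygonLabel(class_id=class_id, vertices=verts)


def polygon_to_mask(label: PolygonLabel, height: int, width: int) -> BinaryMask:
    """Rasterize a filled polygon: pixel (r, c) is true iff its center
    ``(c + 0.5, r + 0.5)`` lies inside or on the polygon boundary."""
    if height < 1 or width < 1:
        raise FormatError("mask dimensions must be positive")
    verts = label.vertices * np.array([width, height], dtype=float)
    poly = Polygon(verts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.area == 0:
        return BinaryMask(np.zeros((height, width), dtype=bool))
    cc, rr = np.meshgrid(
        np.arange(width, dtype=float) + 0.5,
        np.arange(height, dtype=float) + 0.5,
    )
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel())
    return BinaryMask(inside.reshape(height, width))


# ---------------------------------------------------------------------------
# label text files and manifests
# ---------------------------------------------------------------------------


def write_polygon_labels(labels: Sequence[PolygonLabel], path: str | Path) -> None:
    """One line per instance: ``class_id x1 y1 x2 y2 ...``, 6 decimals."""
    lines = []
    for lab in labels:
        coords = " ".join(f"{v:.6f}" for v in lab.vertices.ravel())
        lines.append(f"{lab.class_id} {coords}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_polygon_labels(path: str | Path) -> list[PolygonLabel]:
    path = Path(path)
    if not path.is_file():
        raise InputError(f"label file not found: {path}")
    labels = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 7 or (len(fields) - 1) % 2 != 0:
            raise FormatError(
                f"{path}:{lineno}: expected 'class_id x1 y1 x2 y2 x3 y3 ...'"
            )
        try:
            cid = int(fields[0])
            coords = np.array([float(f) for f in fields[1:]], dtype=float)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
        labels.append(PolygonLabel(class_id=cid, vertices=coords.reshape(-1, 2)))
    return labels


MANIFEST_COLUMNS = ["record_id", "brightfield", "cd61", "cd45", "class", "phenotype"]


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    extra = [c for c in df.columns if c not in MANIFEST_COLUMNS]
    df.to_csv(path, index=False, columns=MANIFEST_COLUMNS + extra, lineterminator="\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise InputError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"record_id": str}, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} missing columns: {missing}")
    return df


def load_record_from_manifest_row(
    row: pd.Series, root: str | Path = "."
) -> MultiChannelRecord:
    """Load a record whose image paths are given relative to *root*."""
    root = Path(root)
    rec = read_record(
        root / row["brightfield"],
        root / row["cd61"],
        root / row["cd45"],
        record_id=str(row["record_id"]),
    )
    if row.get("class"):
        rec.truth_class = ClusterClass(row["class"])
    if row.get("phenotype"):
        rec.truth_phenotype = PhenotypeLabel(row["phenotype"])
    mask_col = row.get("mask", "")
    if mask_col:
        rec = MultiChannelRecord(
            record_id=rec.record_id,
            brightfield=rec.brightfield,
            cd61=rec.cd61,
            cd45=rec.cd45,
            truth_mask=read_mask(root / mask_col),
            truth_class=rec.truth_class,
            truth_phenotype=rec.truth_phenotype,
        )
    return rec
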