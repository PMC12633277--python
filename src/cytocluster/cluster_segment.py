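"""Brightfield cluster delineation behind a pluggable backend contract.

Any backend is a callable ``(brightfield: ChannelImage, cfg) ->
SegmentationResult`` whose instances union to its mask.  The built-in
``reference`` backend is a classical segmenter: Otsu binarization (with
inversion, cells being darker than the background), morphological open +
close, hole filling, connected components, and an area filter.  Learned
detectors can be registered under their own name and used interchangeably
by the downstream phenotyping stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import (
    binary_closing,
    binary_fill_holes,
    binary_opening,
    distance_transform_edt,
)
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import convex_hull_image, disk, h_maxima

from cytocluster.errors import FormatError, ParameterError
from cytocluster.imageio_core import BinaryMask, ChannelImage, ClusterClass

__all__ = [
    "SegmenterConfig",
    "SegmentationResult",
    "ClusterRules",
    "segment_clusters",
    "classify_cluster",
    "register_backend",
    "get_backend",
]


@dataclass(frozen=True)
class SegmenterConfig:
    """Reference-segmenter knobs.

    ``min_contrast`` guards against pure-noise frames: if the mean
    foreground/background intensity separation at the Otsu threshold is
    below this value, the frame is treated as empty.
    """

    min_component_area: int = 30
    morph_radius: int = 2
    invert: bool = True
    fill_holes: bool = True
    min_contrast: float = 20.0

    def __post_init__(self) -> None:
        if self.min_component_area < 1:
            raise ParameterError("min_component_area must be >= 1")
        if self.morph_radius < 0:
            raise ParameterError("morph_radius must be >= 0")


@dataclass(frozen=True)
class SegmentationResult:
    """Accepted components, largest first, with reference confidences."""

    mask: BinaryMask
    instances: tuple[BinaryMask, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.instances) != len(self.scores):
            raise FormatError("scores length must equal instances length")
        if self.instances:
            union = np.zeros_like(self.mask.grid)
            for inst in self.instances:
                union |= inst.grid
            if not np.array_equal(union, self.mask.grid):
                raise FormatError("union of instances must equal the mask")
        elif self.mask.area != 0:
            raise FormatError("empty instance list requires an empty mask")

    @property
    def largest(self) -> BinaryMask | None:
        return self.instances[0] if self.instances else None

    @classmethod
    def empty(cls, height: int, width: int) -> "SegmentationResult":
        return cls(
            mask=BinaryMask(np.zeros((height, width), dtype=bool)),
            instances=(),
            scores=(),
        )


def segment_clusters(
    brightfield: ChannelImage, cfg: SegmenterConfig = SegmenterConfig()
) -> SegmentationResult:
    """Reference classical segmentation of a grayscale brightfield frame.

    Deterministic.  Components are sorted by area descending (ties broken
    by the lower top-left raster index); scores are component area divided
    by the largest component's area.
    """
    if brightfield.is_rgb:
        raise FormatError("segment_clusters expects a grayscale brightfield image")
    img = brightfield.pixels.astype(float)
    h, w = img.shape
    if img.max() == img.min():  # constant frame: no threshold exists
        return SegmentationResult.empty(h, w)
    # work on an image where objects are dark
    work = img if cfg.invert else img.max() - img
    thr = threshold_otsu(work)
    # Otsu can split between two object intensities instead of objects vs
    # background; extend the threshold while the bright side still contains
    # a small, high-contrast dark population
    for _ in range(4):
        rest = work[work >= thr]
        if rest.size < 64 or rest.max() == rest.min():
            break
        t2 = threshold_otsu(rest)
        sub = rest[rest < t2]
        keep = rest[rest >= t2]
        if (
            t2 > thr
            and sub.size > 0
            and sub.size <= 0.25 * work.size
            and keep.mean() - sub.mean() >= cfg.min_contrast
        ):
            thr = t2
        else:
            break
    binary = work < thr
    if not binary.any() or binary.all():
        return SegmentationResult.empty(h, w)
    fg_mean = work[binary].mean()
    bg_mean = work[~binary].mean()
    if bg_mean - fg_mean < cfg.min_contrast:
        return SegmentationResult.empty(h, w)
    if cfg.morph_radius > 0:
        selem = disk(cfg.morph_radius)
        binary = binary_opening(binary, structure=selem)
        binary = binary_closing(binary, structure=selem)
    if cfg.fill_holes:
        binary = binary_fill_holes(binary)
    labels = cc_label(binary, connectivity=2)
    comps: list[tuple[int, int, np.ndarray]] = []  # (area, first raster idx, grid)
    for lab in range(1, labels.max() + 1):
        grid = labels == lab
        area = int(grid.sum())
        if area < cfg.min_component_area:
            continue
        first_idx = int(np.flatnonzero(grid.ravel())[0])
        comps.append((area, first_idx, grid))
    if not comps:
        return SegmentationResult.empty(h, w)
    comps.sort(key=lambda t: (-t[0], t[1]))
    largest_area = comps[0][0]
    union = np.zeros((h, w), dtype=bool)
    for _, _, grid in comps:
        union |= grid
    return SegmentationResult(
        mask=BinaryMask(union),
        instances=tuple(BinaryMask(grid) for _, _, grid in comps),
        scores=tuple(area / largest_area for area, _, _ in comps),
    )


@dataclass(frozen=True)
class ClusterRules:
    """Stand-in rules for the stage-1 cluster / non-cluster decision.

    A frame is called a cluster when its largest segmented component is
    consistent with >= 2 touching cells: big enough, and either visibly
    non-convex (solidity at most ``max_solidity``) or containing at least
    ``min_cores`` distinct cell cores.  Cores are counted as the h-maxima
    (depth ``core_depth_px``) of the component's Euclidean distance
    transform — the waist between two touching cells separates their
    distance peaks, whereas a lone convex cell has exactly one.
    """

    min_cluster_area: int = 100
    max_solidity: float = 0.955
    min_cores: int = 2
    core_depth_px: float = 1.25


def count_cell_cores(component: np.ndarray, rules: ClusterRules = ClusterRules()) -> int:
    """Number of distance-transform peak regions inside the component."""
    dt = distance_transform_edt(component)
    peaks = h_maxima(dt, rules.core_depth_px) & component
    return int(cc_label(peaks, connectivity=2).max())


def classify_cluster(
    seg: SegmentationResult,
    rules: ClusterRules = ClusterRules(),
    brightfield: ChannelImage | None = None,
) -> ClusterClass:
    """Decide cluster vs non-cluster from the largest segmented component.

    The brightfield image is accepted for API symmetry with learned
    backends but is not needed by the reference rules.
    """
    largest = seg.largest
    if largest is None or largest.area < rules.min_cluster_area:
        return ClusterClass.NON_CLUSTER
    grid = largest.grid
    hull_area = int(convex_hull_image(grid).sum())
    solidity = largest.area / hull_area if hull_area else 1.0
    if solidity <= rules.max_solidity:
        return ClusterClass.CLUSTER
    if count_cell_cores(grid, rules) >= rules.min_cores:
        return ClusterClass.CLUSTER
    return ClusterClass.NON_CLUSTER


# ---------------------------------------------------------------------------
# backend registry
# ---------------------------------------------------------------------------

Backend = Callable[[ChannelImage, SegmenterConfig], SegmentationResult]

_BACKENDS: dict[str, Backend] = {"reference": segment_clusters}


def register_backend(name: str, backend: Backend) -> None:
    """Register an external segmentation adapter under *name*."""
    _BACKENDS[name] = backend


def get_backend(name: str) -> Backend:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise ParameterError(
            f"unknown segmentation backend {name!r}; known: {sorted(_BACKENDS)}"
        ) from None
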