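"""Synthetic multi-channel records with exact ground truth.

Emulates the scene taxonomy seen on a real imaging flow cytometer: blank
fields, single cells, multiple separated cells, and touching/overlapping
cell clusters, with fluorescence staining that covers the cluster, covers
it partially, or lies entirely outside it (a staining artifact caused by
debris).

Cells are rendered as filled dark ellipses (intensity ~ U[40, 120]) on a
bright noisy background (N(background_level, noise_sigma), default level
200).  "Cluster" means the cells form a connected contact graph (pairwise
centroid distance below the sum of radii along a placement chain);
"separated" means every pairwise gap is at least 5 px.  Stain is painted
directly in the HSV dialect of :mod:`cytocluster.fluor_extract` (hue 60 for
green, 30 for yellow on the 0-179 scale), so painted pixels re-extract
exactly in the noise-free case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk

from cytocluster.errors import GenerationError, InputError, ParameterError
from cytocluster.fluor_extract import hsv255_to_rgb
from cytocluster.imageio_core import (
    BinaryMask,
    ChannelImage,
    ClusterClass,
    MultiChannelRecord,
    PhenotypeLabel,
    write_image,
    write_manifest,
    write_mask,
)

__all__ = [
    "SceneSpec",
    "StainSpec",
    "generate_scene",
    "apply_staining",
    "generate_labeled_record",
    "generate_dataset",
    "GREEN_HUE",
    "YELLOW_HUE",
]

GREEN_HUE = 60  # pure green on the 0-179 half-degree scale
YELLOW_HUE = 30
STAIN_SATURATION = 220
SCENE_KINDS = ("blank", "single_cell", "separated_cells", "cluster")
NON_CLUSTER_KINDS = ("blank", "single_cell", "separated_cells")
_MIN_SEPARATION_GAP = 5.0  # px; must exceed the 4 px a radius-2 closing can bridge
_ARTIFACT_CLEARANCE = 2  # px, artifact blobs keep this distance from the mask


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of one synthetic brightfield scene."""

    kind: str = "cluster"
    n_cells: int = 3
    cell_radius: tuple[float, float] = (8.0, 14.0)
    overlap_frac: float = 0.25
    background_level: int = 200
    noise_sigma: float = 5.0
    height: int = 128
    width: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENE_KINDS:
            raise ParameterError(f"unknown scene kind {self.kind!r}")
        if self.kind == "blank" and self.n_cells != 0:
            raise ParameterError("blank scenes must have n_cells=0")
        if self.kind == "single_cell" and self.n_cells != 1:
            raise ParameterError("single_cell scenes must have n_cells=1")
        if self.kind == "cluster" and self.n_cells < 2:
            raise ParameterError("cluster scenes need n_cells >= 2")
        if self.kind == "separated_cells" and self.n_cells < 2:
            raise ParameterError("separated_cells scenes need n_cells >= 2")
        if not (0.0 <= self.overlap_frac < 1.0):
            raise ParameterError("overlap_frac must lie in [0, 1)")


@dataclass(frozen=True)
class StainSpec:
    """Staining plan for one record.

    ``coverage_frac`` of the cluster mask area is painted per implied
    channel (platelet -> green, wbc -> yellow, wbc_platelet -> both,
    rbc -> neither); ``artifact_area_px`` stained pixels are additionally
    placed strictly outside the mask.  ``stain_hue`` selects the channel
    that receives the artifact when the phenotype implies none (RBC).
    """

    target_phenotype: PhenotypeLabel = PhenotypeLabel.PLATELET_CLUSTER
    coverage_frac: float = 0.6
    artifact_area_px: int = 0
    stain_hue: str = "green"
    intensity: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage_frac <= 1.0):
            raise ParameterError("coverage_frac must lie in [0, 1]")
        if self.artifact_area_px < 0:
            raise ParameterError("artifact_area_px must be >= 0")
        if self.stain_hue not in ("green", "yellow"):
            raise ParameterError("stain_hue must be 'green' or 'yellow'")
        if not (0 <= self.intensity <= 255):
            raise ParameterError("intensity must lie in [0, 255]")


# ---------------------------------------------------------------------------
# brightfield scenes
# ---------------------------------------------------------------------------


def _cell_footprint(
    center: tuple[float, float],
    radius: float,
    aspect: float,
    angle: float,
    shape: tuple[int, int],
) -> np.ndarray:
    grid = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(
        center[0], center[1], radius, radius * aspect, shape=shape, rotation=angle
    )
    grid[rr, cc] = True
    return grid


def _ellipse_support(radius: float, aspect: float, angle: float, theta: float) -> float:
    """Half-width of the ellipse (semi-axes radius, radius*aspect, rotated by
    *angle*) along the direction *theta*."""
    a, b = radius, radius * aspect
    rel = theta - angle
    return math.sqrt((a * math.cos(rel)) ** 2 + (b * math.sin(rel)) ** 2)


def _place_cells(spec: SceneSpec, rng: np.random.Generator):
    """Sample geometry satisfying the kind's contact constraints.

    For clusters, each new cell is attached to a previously placed one at a
    centroid distance of ``(1 - overlap_frac)`` times the sum of the two
    ellipses' supports along the placement direction, so the pair genuinely
    overlaps by the requested depth regardless of shape and rotation.
    """
    h, w = spec.height, spec.width
    r_lo, r_hi = spec.cell_radius
    for _attempt in range(50):
        radii = rng.uniform(r_lo, r_hi, size=spec.n_cells)
        aspects = rng.uniform(0.85, 1.0, size=spec.n_cells)
        angles = rng.uniform(0, math.pi, size=spec.n_cells)
        margin = float(radii.max()) + 2.0
        if 2 * margin >= min(h, w):
            raise GenerationError("cells too large for the frame")
        centers: list[tuple[float, float]] = []
        ok = True
        for i in range(spec.n_cells):
            placed = False
            for _try in range(200):
                if spec.kind == "cluster" and centers:
                    j = int(rng.integers(0, len(centers)))
                    theta = rng.uniform(0, 2 * math.pi)
                    d = (1.0 - spec.overlap_frac) * (
                        _ellipse_support(radii[j], aspects[j], angles[j], theta)
                        + _ellipse_support(radii[i], aspects[i], angles[i], theta)
                    )
                    cand = (
                        centers[j][0] + d * math.sin(theta),
                        centers[j][1] + d * math.cos(theta),
                    )
                else:
                    cand = (
                        float(rng.uniform(margin, h - margin)),
                        float(rng.uniform(margin, w - margin)),
                    )
                if not (margin <= cand[0] <= h - margin and margin <= cand[1] <= w - margin):
                    continue
                if spec.kind == "separated_cells":
                    gaps = [
                        math.dist(cand, c) - radii[i] - radii[k]
                        for k, c in enumerate(centers)
                    ]
                    if any(g < _MIN_SEPARATION_GAP for g in gaps):
                        continue
                if spec.kind == "cluster" and centers:
                    # the requested overlap depth is a bound for EVERY pair,
                    # not just the attachment parent, so siblings in the
                    # contact chain cannot collapse onto each other
                    too_deep = False
                    for k, c in enumerate(centers):
                        if k == j:
                            continue
                        dk = math.dist(cand, c)
                        theta_k = math.atan2(cand[0] - c[0], cand[1] - c[1])
                        min_d = (1.0 - spec.overlap_frac) * (
                            _ellipse_support(radii[k], aspects[k], angles[k], theta_k)
                            + _ellipse_support(radii[i], aspects[i], angles[i], theta_k)
                        )
                        if dk < min_d:
                            too_deep = True
                            break
                    if too_deep:
                        continue
                centers.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return centers, radii, aspects, angles
    raise GenerationError(
        f"could not pack {spec.n_cells} cells of radius {spec.cell_radius} "
        f"into a {h}x{w} frame after bounded retries"
    )


def _dark_fluor_plane(shape: tuple[int, int], noisy: bool, rng: np.random.Generator) -> np.ndarray:
    if noisy:
        return rng.integers(0, 8, size=shape + (3,)).astype(np.uint8)
    return np.zeros(shape + (3,), dtype=np.uint8)


def generate_scene(spec: SceneSpec) -> MultiChannelRecord:
    """Render one brightfield scene with dark unstained fluorescence channels.

    ``truth_mask`` is the union of cell footprints (empty for blank scenes);
    ``truth_class`` is cluster iff ``spec.kind == "cluster"``.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    bf = np.full((h, w), float(spec.background_level))
    mask = np.zeros((h, w), dtype=bool)
    if spec.n_cells > 0:
        centers, radii, aspects, angles = _place_cells(spec, rng)
        for center, radius, aspect, angle in zip(centers, radii, aspects, angles):
            foot = _cell_footprint(
                center, radius, aspect=float(aspect), angle=float(angle), shape=(h, w)
            )
            bf[foot] = float(rng.uniform(40, 120))
            mask |= foot
    if spec.noise_sigma > 0:
        bf = bf + rng.normal(0.0, spec.noise_sigma, size=bf.shape)
    bf_img = ChannelImage(np.clip(np.rint(bf), 0, 255).astype(np.uint8))
    noisy = spec.noise_sigma > 0
    return MultiChannelRecord(
        record_id=f"scene-{spec.kind}-{spec.seed}",
        brightfield=bf_img,
        cd61=ChannelImage(_dark_fluor_plane((h, w), noisy, rng)),
        cd45=ChannelImage(_dark_fluor_plane((h, w), noisy, rng)),
        truth_mask=BinaryMask(mask),
        truth_class=(
            ClusterClass.CLUSTER if spec.kind == "cluster" else ClusterClass.NON_CLUSTER
        ),
    )


# ---------------------------------------------------------------------------
# staining
# ---------------------------------------------------------------------------

_CHANNELS_BY_PHENOTYPE: Mapping[PhenotypeLabel, tuple[str, ...]] = {
    PhenotypeLabel.PLATELET_CLUSTER: ("green",),
    PhenotypeLabel.WBC_CLUSTER: ("yellow",),
    PhenotypeLabel.WBC_PLATELET_CLUSTER: ("green", "yellow"),
    PhenotypeLabel.RBC_CLUSTER: (),
}


def _compact_subset(
    candidates: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick n candidate pixels forming a compact blob around a random seed.

    *candidates* is an (m, 2) array of (row, col) coordinates; returns an
    (n, 2) subset ordered by distance from the seed pixel.
    """
    seed_idx = int(rng.integers(0, len(candidates)))
    d = np.linalg.norm(candidates - candidates[seed_idx], axis=1)
    order = np.argsort(d, kind="stable")
    return candidates[order[:n]]


def _paint(img: ChannelImage, coords: np.ndarray, hue: int, intensity: int) -> ChannelImage:
    rgb = hsv255_to_rgb(hue, STAIN_SATURATION, intensity)
    px = img.pixels.copy()
    px[coords[:, 0], coords[:, 1]] = rgb
    return ChannelImage(px)


def apply_staining(
    record: MultiChannelRecord, stain: StainSpec, set_truth: bool = True
) -> MultiChannelRecord:
    """Paint fluorescence stain into the record per the staining plan.

    Returns a new record; sets ``truth_phenotype`` to the label the overlap
    rules should recover (the target phenotype, or excluded-artifact when
    the only painted pixels lie wholly outside the cluster mask).  With
    ``set_truth=False`` the existing truth label is kept, which allows
    layering sub-threshold spurious stain on top of a genuine one.
    """
    channels = _CHANNELS_BY_PHENOTYPE[stain.target_phenotype]
    needs_mask = (stain.coverage_frac > 0 and channels) or stain.artifact_area_px > 0
    if needs_mask and (record.truth_mask is None or record.truth_mask.area == 0):
        raise InputError(
            "staining with coverage or artifacts requires a non-empty truth_mask"
        )
    rng = np.random.default_rng(stain.seed)
    mask = record.truth_mask.grid if record.truth_mask is not None else None
    cd61, cd45 = record.cd61, record.cd45
    painted_inside = False

    for channel in channels:
        if stain.coverage_frac <= 0:
            continue
        inside = np.argwhere(mask)
        # ceil keeps the realized overlap fraction at or above the request
        n = min(len(inside), int(np.ceil(stain.coverage_frac * len(inside))))
        coords = _compact_subset(inside, n, rng)
        hue = GREEN_HUE if channel == "green" else YELLOW_HUE
        if channel == "green":
            cd61 = _paint(cd61, coords, hue, stain.intensity)
        else:
            cd45 = _paint(cd45, coords, hue, stain.intensity)
        painted_inside = True

    if stain.artifact_area_px > 0:
        clearance = binary_dilation(mask, structure=disk(_ARTIFACT_CLEARANCE))
        outside = np.argwhere(~clearance)
        if len(outside) < stain.artifact_area_px:
            raise GenerationError("not enough room outside the mask for the artifact")
        coords = _compact_subset(outside, stain.artifact_area_px, rng)
        artifact_channels = channels if channels else (stain.stain_hue,)
        for channel in artifact_channels:
            hue = GREEN_HUE if channel == "green" else YELLOW_HUE
            if channel == "green":
                cd61 = _paint(cd61, coords, hue, stain.intensity)
            else:
                cd45 = _paint(cd45, coords, hue, stain.intensity)

    if not set_truth:
        truth = record.truth_phenotype
    elif painted_inside:
        truth = stain.target_phenotype
    elif stain.artifact_area_px > 0:
        truth = PhenotypeLabel.EXCLUDED_ARTIFACT
    else:
        truth = PhenotypeLabel.RBC_CLUSTER
    return MultiChannelRecord(
        record_id=record.record_id,
        brightfield=record.brightfield,
        cd61=cd61,
        cd45=cd45,
        truth_mask=record.truth_mask,
        truth_class=record.truth_class,
        truth_phenotype=truth,
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def generate_labeled_record(
    record_id: str,
    cluster: bool,
    phenotype: PhenotypeLabel | None,
    seed: int,
    *,
    noise_sigma: float = 5.0,
    coverage_frac: float | None = None,
    artifact_area_px: int = 0,
    stain_intensity: int = 200,
    n_cells: int | None = None,
    overlap_frac: float = 0.25,
    height: int = 128,
    width: int = 128,
) -> MultiChannelRecord:
    """One labeled record: a scene plus (for clusters) its staining."""
    rng = np.random.default_rng(seed)
    if cluster:
        spec = SceneSpec(
            kind="cluster",
            n_cells=n_cells if n_cells is not None else int(rng.integers(2, 5)),
            overlap_frac=overlap_frac,
            noise_sigma=noise_sigma,
            height=height,
            width=width,
            seed=int(rng.integers(0, 2**31)),
        )
        record = generate_scene(spec)
        cov = coverage_frac if coverage_frac is not None else float(rng.uniform(0.4, 0.9))
        stain = StainSpec(
            target_phenotype=phenotype or PhenotypeLabel.RBC_CLUSTER,
            coverage_frac=cov if phenotype != PhenotypeLabel.RBC_CLUSTER else 0.0,
            artifact_area_px=artifact_area_px,
            stain_hue="green" if rng.random() < 0.5 else "yellow",
            intensity=stain_intensity,
            seed=int(rng.integers(0, 2**31)),
        )
        record = apply_staining(record, stain)
    else:
        kind = NON_CLUSTER_KINDS[int(rng.integers(0, len(NON_CLUSTER_KINDS)))]
        n = {"blank": 0, "single_cell": 1}.get(kind, int(rng.integers(2, 4)))
        spec = SceneSpec(
            kind=kind,
            n_cells=n,
            noise_sigma=noise_sigma,
            height=height,
            width=width,
            seed=int(rng.integers(0, 2**31)),
        )
        record = generate_scene(spec)
    return replace_record_id(record, record_id)


def replace_record_id(record: MultiChannelRecord, record_id: str) -> MultiChannelRecord:
    return MultiChannelRecord(
        record_id=record_id,
        brightfield=record.brightfield,
        cd61=record.cd61,
        cd45=record.cd45,
        truth_mask=record.truth_mask,
        truth_class=record.truth_class,
        truth_phenotype=record.truth_phenotype,
    )


_PHENOTYPES = (
    PhenotypeLabel.RBC_CLUSTER,
    PhenotypeLabel.PLATELET_CLUSTER,
    PhenotypeLabel.WBC_CLUSTER,
    PhenotypeLabel.WBC_PLATELET_CLUSTER,
)


def generate_dataset(
    out_dir: str | Path,
    n_records: int,
    class_mix: Mapping[str, float] | None = None,
    phenotype_mix: Mapping[PhenotypeLabel, float] | None = None,
    artifact_rate: float = 0.0,
    seed: int = 0,
    *,
    noise_sigma: float = 5.0,
    artifact_area_px: int = 120,
) -> pd.DataFrame:
    """Write a synthetic dataset (images, masks, manifest CSV) to *out_dir*.

    ``class_mix`` gives cluster/non_cluster proportions (default 50/50);
    ``phenotype_mix`` the per-phenotype proportions among cluster records
    (default uniform over the four phenotypes).  With probability
    ``artifact_rate`` a cluster record is turned into an artifact-only
    record: no in-mask stain, ``artifact_area_px`` stained pixels wholly
    outside the mask.  Deterministic given *seed*; returns the manifest.
    """
    if n_records < 1:
        raise ParameterError("n_records must be >= 1")
    class_mix = dict(class_mix or {"cluster": 0.5, "non_cluster": 0.5})
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ParameterError("class_mix must sum to 1")
    phenotype_mix = dict(
        phenotype_mix or {p: 0.25 for p in _PHENOTYPES}
    )
    if abs(sum(phenotype_mix.values()) - 1.0) > 1e-9:
        raise ParameterError("phenotype_mix must sum to 1")

    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc

    rng = np.random.default_rng(seed)
    phenos = list(phenotype_mix)
    pheno_p = np.array([phenotype_mix[p] for p in phenos])
    rows = []
    for i in range(n_records):
        rid = f"rec{i:05d}"
        is_cluster = rng.random() < class_mix.get("cluster", 0.0)
        rec_seed = int(rng.integers(0, 2**31))
        if is_cluster:
            artifact_only = rng.random() < artifact_rate
            pheno = phenos[int(rng.choice(len(phenos), p=pheno_p))]
            record = generate_labeled_record(
                rid,
                cluster=True,
                phenotype=pheno,
                seed=rec_seed,
                noise_sigma=noise_sigma,
                coverage_frac=0.0 if artifact_only else None,
                artifact_area_px=artifact_area_px if artifact_only else 0,
            )
        else:
            record = generate_labeled_record(
                rid, cluster=False, phenotype=None, seed=rec_seed,
                noise_sigma=noise_sigma,
            )
        paths = {
            "brightfield": f"images/{rid}_bf.png",
            "cd61": f"images/{rid}_cd61.png",
            "cd45": f"images/{rid}_cd45.png",
            "mask": f"masks/{rid}_mask.png",
        }
        write_image(record.brightfield, out_dir / paths["brightfield"])
        write_image(record.cd61, out_dir / paths["cd61"])
        write_image(record.cd45, out_dir / paths["cd45"])
        write_mask(record.truth_mask, out_dir / paths["mask"])
        rows.append(
            {
                "record_id": rid,
                **paths,
                "class": record.truth_class.value,
                "phenotype": (
                    record.truth_phenotype.value if record.truth_phenotype else ""
                ),
            }
        )
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
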