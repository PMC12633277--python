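"""Mask-overlap phenotyping of a segmented cluster.

The overlap percentage of a stain mask against the brightfield cluster mask
is ``100 * |cluster AND stain| / |cluster|`` — the denominator is always
the cluster-mask area.  Per channel the state is:

* ``no_stain`` — the stain mask is empty;
* ``artifact`` — stain exists but none of it touches the cluster;
* ``present`` — overlap percentage at or above the threshold (default 15%);
* ``absent`` — some overlap, but below the threshold.

Decision table (green = CD61/platelet, yellow = CD45/WBC): both present ->
WBC+platelet cluster; green only -> platelet cluster; yellow only -> WBC
cluster; no channel present, at least one artifact, and no channel with
positive sub-threshold overlap -> excluded artifact; anything else (no
stain at all, or only sub-threshold overlap) -> RBC cluster.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from cytocluster.errors import EmptyRegionError, ParameterError
from cytocluster.fluor_extract import (
    StainChannel,
    extract_stain_mask,
    green_channel,
    yellow_channel,
)
from cytocluster.imageio_core import (
    BinaryMask,
    MultiChannelRecord,
    PhenotypeLabel,
)

__all__ = [
    "PhenotypeConfig",
    "ChannelState",
    "OverlapReport",
    "overlap_percentage",
    "channel_state",
    "decide_label",
    "classify_phenotype",
]


class ChannelState(enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    ARTIFACT = "artifact"
    NO_STAIN = "no_stain"


@dataclass(frozen=True)
class PhenotypeConfig:
    overlap_threshold_pct: float = 15.0
    artifact_requires_zero_overlap: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_threshold_pct <= 100.0):
            raise ParameterError("overlap_threshold_pct must lie in (0, 100]")


@dataclass(frozen=True)
class OverlapReport:
    overlap_pct_green: float
    overlap_pct_yellow: float
    green_state: ChannelState
    yellow_state: ChannelState
    label: PhenotypeLabel


def overlap_percentage(cluster_mask: BinaryMask, stain_mask: BinaryMask) -> float:
    """100 x |cluster AND stain| / |cluster| (counts of true pixels)."""
    if cluster_mask.area == 0:
        raise EmptyRegionError("overlap percentage undefined for an empty cluster mask")
    inter = (cluster_mask & stain_mask).area
    return 100.0 * inter / cluster_mask.area


def channel_state(
    cluster_mask: BinaryMask,
    stain_mask: BinaryMask,
    cfg: PhenotypeConfig = PhenotypeConfig(),
) -> tuple[ChannelState, float]:
    """Classify one channel's stain evidence; returns (state, overlap pct)."""
    if stain_mask.area == 0:
        return ChannelState.NO_STAIN, 0.0
    pct = overlap_percentage(cluster_mask, stain_mask)
    if pct == 0.0:
        return ChannelState.ARTIFACT, 0.0
    if pct >= cfg.overlap_threshold_pct:
        return ChannelState.PRESENT, pct
    return ChannelState.ABSENT, pct


def decide_label(green: ChannelState, yellow: ChannelState) -> PhenotypeLabel:
    """Total, deterministic decision table over the two channel states."""
    g_present = green is ChannelState.PRESENT
    y_present = yellow is ChannelState.PRESENT
    if g_present and y_present:
        return PhenotypeLabel.WBC_PLATELET_CLUSTER
    if g_present:
        return PhenotypeLabel.PLATELET_CLUSTER
    if y_present:
        return PhenotypeLabel.WBC_CLUSTER
    any_artifact = ChannelState.ARTIFACT in (green, yellow)
    any_subthreshold = ChannelState.ABSENT in (green, yellow)
    if any_artifact and not any_subthreshold:
        return PhenotypeLabel.EXCLUDED_ARTIFACT
    return PhenotypeLabel.RBC_CLUSTER


def classify_phenotype(
    record: MultiChannelRecord,
    cluster_mask: BinaryMask,
    cfg: PhenotypeConfig = PhenotypeConfig(),
    green: StainChannel | None = None,
    yellow: StainChannel | None = None,
    apply_morphology: bool = True,
) -> OverlapReport:
    """Extract both stain masks, score their overlap, and assign the label."""
    green = green if green is not None else green_channel()
    yellow = yellow if yellow is not None else yellow_channel()
    g_mask = extract_stain_mask(record.cd61, green, apply_morphology=apply_morphology)
    y_mask = extract_stain_mask(record.cd45, yellow, apply_morphology=apply_morphology)
    g_state, g_pct = channel_state(cluster_mask, g_mask, cfg)
    y_state, y_pct = channel_state(cluster_mask, y_mask, cfg)
    return OverlapReport(
        overlap_pct_green=g_pct,
        overlap_pct_yellow=y_pct,
        green_state=g_state,
        yellow_state=y_state,
        label=decide_label(g_state, y_state),
    )
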