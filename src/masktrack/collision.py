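"""Collision detection and cluster separation.

A *collision* is a segmentation failure: two or more objects correctly
detected as individuals at time t are merged into a single labeled region at
time t+1.  A t+1 label is declared a collision cluster when at least two
t-labels each have a large fraction of their own area covered by it.  The
cluster is then split back into one part per source by a feedback loop from
tracking to the mask: each part is seeded with the cluster's intersection
with its source's t-footprint, and the remaining cluster pixels join the
seed that is nearest by within-cluster (geodesic) distance, so splits
respect the cluster's geometry around concavities.

When fusion tracking is enabled the same many-to-one events are genuine
merges (e.g. stem-cell colonies): masks are never modified and the events
surface as fusion edges in the lineage instead.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import TrackingConfig
from .cost import OverlapTable
from .io import LabeledMask

__all__ = ["CollisionEvent", "detect_collisions", "separate_cluster"]


@dataclasses.dataclass(frozen=True)
class CollisionEvent:
    """A many-to-one merge: ``sources`` (labels at t) -> ``cluster`` (label at t+1).

    ``is_fusion`` marks the event as a genuine merge to be recorded in the
    lineage rather than split in the mask.
    """

    cluster: int
    sources: frozenset[int]
    is_fusion: bool = False


def detect_collisions(
    overlaps: OverlapTable,
    feat_t: pd.DataFrame,
    feat_t1: pd.DataFrame,
    config: TrackingConfig,
) -> list[CollisionEvent]:
    """Find t+1 labels that merge two or more t objects.

    A label j at t+1 is a collision cluster when >= 2 labels at t each
    overlap j by at least ``min_collision_overlap`` of their own area; the
    sources are exactly those labels.  With ``enable_fusion`` the events are
    tagged as fusions and no splitting happens downstream.
    """
    events: list[CollisionEvent] = []
    for j in sorted(int(x) for x in feat_t1.index):
        sources = []
        for i, shared in sorted(overlaps.sources_of(j).items()):
            frac = shared / float(feat_t.at[i, "area"])
            if frac >= config.min_collision_overlap:
                sources.append(i)
        if len(sources) >= 2:
            events.append(
                CollisionEvent(j, frozenset(sources), is_fusion=config.enable_fusion)
            )
    return events


_NEIGHBORS_8 = [
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
]


def _geodesic_partition(cluster: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Partition a boolean ``cluster`` among seed labels by geodesic distance.

    ``seeds`` holds positive part labels on seed pixels, 0 elsewhere; the
    result assigns every cluster pixel a part label.  Propagation is a
    level-synchronous multi-source BFS restricted to the cluster with
    8-connectivity; ties at equal distance go to the lower part label
    (labels are processed in ascending order within each level, and a pixel
    is claimed only once).
    """
    assigned = seeds.copy()
    part_labels = np.unique(seeds[seeds > 0])
    while True:
        unassigned = cluster & (assigned == 0)
        if not unassigned.any():
            break
        claims = np.zeros_like(assigned)
        grew = False
        for part in part_labels:  # ascending: lower label wins ties
            region = assigned == part
            reach = np.zeros_like(region)
            for dr, dc in _NEIGHBORS_8:
                shifted = np.zeros_like(region)
                src = region[
                    max(0, -dr) : region.shape[0] - max(0, dr),
                    max(0, -dc) : region.shape[1] - max(0, dc),
                ]
                shifted[
                    max(0, dr) : region.shape[0] - max(0, -dr),
                    max(0, dc) : region.shape[1] - max(0, -dc),
                ] = src
                reach |= shifted
            newly = reach & unassigned & (claims == 0)
            if newly.any():
                claims[newly] = part
                grew = True
        if not grew:
            # isolated cluster pixels unreachable from any seed (disconnected
            # debris): give them to the lowest part label to conserve pixels
            claims[unassigned] = part_labels[0]
        assigned[claims > 0] = claims[claims > 0]
    return assigned


def separate_cluster(
    mask_t: LabeledMask,
    mask_t1: LabeledMask,
    event: CollisionEvent,
    new_labels: dict[int, int] | None = None,
) -> tuple[LabeledMask, dict[int, int]]:
    """Split a collision cluster in the t+1 mask into one part per source.

    Seeds are the intersections of the cluster with each source's
    t-footprint; remaining cluster pixels join the geodesically nearest
    seed.  The cluster's total pixel count is conserved and every part is
    non-empty.  Returns the modified t+1 mask and a map
    ``source label (t) -> new part label (t+1)``.

    ``new_labels`` optionally fixes the part labels; by default fresh labels
    above the current t+1 maximum are used, assigned to sources in
    ascending order.
    """
    if event.is_fusion:
        raise ValueError("fusion events must not be separated")
    pix_t1 = mask_t1.pixels
    cluster = pix_t1 == event.cluster
    if not cluster.any():
        raise RuntimeError(f"cluster label {event.cluster} absent from t+1 mask")

    sources = sorted(event.sources)
    if new_labels is None:
        base = int(pix_t1.max())
        new_labels = {src: base + k + 1 for k, src in enumerate(sources)}

    seeds = np.zeros_like(pix_t1)
    for src in sources:
        seed = cluster & (mask_t.pixels == src)
        if not seed.any():
            raise RuntimeError(
                f"source {src} has no footprint inside cluster {event.cluster}"
            )
        seeds[seed] = new_labels[src]

    parts = _geodesic_partition(cluster, seeds)
    assert (parts[cluster] > 0).all()

    out = pix_t1.copy()
    out[cluster] = parts[cluster]
    return LabeledMask(out, mask_t1.frame_index), dict(new_labels)
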