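"""Mitosis detection from four biological indicators.

A mother m at time t with daughter candidates {d1, d2} at time t+1 is a
mitosis event when all of the following hold:

1. exactly two t+1 objects each overlap m by at least ``min_division_overlap``
   of their own area, with m as their dominant t-source (one -> two);
2. the mother is round: ``circularity(m) >= min_mother_circularity``;
3. the mother barely migrates during division, so the combined overlap of
   the two daughters covers at least ``min_division_overlap`` of her area;
4. the daughters are similar: min/max area ratio and min/max aspect-ratio
   ratio above their thresholds.

All four gates are user-adjustable per cell line.  Splits into more than two
fragments test the two fragments with the largest overlap to the mother as
the daughter pair; remaining fragments are treated as new objects.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .config import TrackingConfig
from .cost import OverlapTable

__all__ = ["MitosisEvent", "detect_mitosis"]


@dataclasses.dataclass(frozen=True)
class MitosisEvent:
    """One division: ``mother`` (label at t) -> ``daughters`` (label pair at t+1)."""

    mother: int
    daughters: tuple[int, int]


def _dominant_source(overlaps: OverlapTable, label_t1: int) -> int | None:
    """The t-label contributing the most pixels to ``label_t1`` (ties: lower label)."""
    sources = overlaps.sources_of(label_t1)
    if not sources:
        return None
    return min(sources, key=lambda i: (-sources[i], i))


def detect_mitosis(
    feat_t: pd.DataFrame,
    feat_t1: pd.DataFrame,
    overlaps: OverlapTable,
    config: TrackingConfig,
) -> list[MitosisEvent]:
    """Detect divisions on one frame pair (run after collision separation).

    Each t+1 object joins at most one event; each mother at most one.
    Mothers are scanned in ascending label order for determinism.
    """
    events: list[MitosisEvent] = []
    claimed_daughters: set[int] = set()

    for m in sorted(int(x) for x in feat_t.index):
        # indicator 2: round mother
        if feat_t.at[m, "circularity"] < config.min_mother_circularity:
            continue

        area_m = float(feat_t.at[m, "area"])
        # daughter candidates: unclaimed t+1 objects overlapping m by at
        # least the threshold fraction of their own area, with m dominant
        candidates: list[tuple[int, int]] = []  # (label, shared px)
        for j, shared in sorted(overlaps.targets_of(m).items()):
            if j in claimed_daughters:
                continue
            if shared / float(feat_t1.at[j, "area"]) < config.min_division_overlap:
                continue
            if _dominant_source(overlaps, j) != m:
                continue
            candidates.append((j, shared))
        if len(candidates) < 2:
            continue
        # >2 fragments: test the two with largest overlap to the mother
        candidates.sort(key=lambda t: (-t[1], t[0]))
        (d1, s1), (d2, s2) = candidates[:2]

        # indicator 3: low migration -> combined overlap covers the mother
        if (s1 + s2) / area_m < config.min_division_overlap:
            continue

        # indicator 4: similar size and shape
        a1, a2 = float(feat_t1.at[d1, "area"]), float(feat_t1.at[d2, "area"])
        if min(a1, a2) / max(a1, a2) < config.min_daughter_size_similarity:
            continue
        r1 = float(feat_t1.at[d1, "aspect_ratio"])
        r2 = float(feat_t1.at[d2, "aspect_ratio"])
        if min(r1, r2) / max(r1, r2) < config.min_daughter_aspect_similarity:
            continue

        events.append(MitosisEvent(m, (min(d1, d2), max(d1, d2))))
        claimed_daughters.update((d1, d2))

    return events
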