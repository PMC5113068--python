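"""Track-accuracy metrics: Alpha, Beta, Jaccard and Jaccard Theta.

Automated tracks are compared against reference tracks in two steps.  First
the objects of the two sets are paired, either by gated centroid distance
(an automated object maps to a reference object when their centroids are
closer than a tolerance ``epsilon``; pairing per frame is an optimal
assignment, not greedy, so the result is order-independent) or by mutual
maximum overlap between labeled masks.  Then four scores are computed, each
in [0, 1] with 0 the worst case (all tracks missed) and 1 the best (all
tracks perfect):

* **Alpha** — proportional to the centroid distances between paired
  positions, ignoring false-positive tracks;
* **Beta** — like Alpha but additionally penalised by false-positive
  positions;
* **Jaccard** — TP/(TP+FN+FP) over frame-to-frame tracking decisions;
* **Jaccard Theta** — the same ratio over complete tracks (a true-positive
  track must follow its reference over the reference's complete lifetime).

False positives exist only in the automated tracking, false negatives only
in the reference, true positives in both.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import LabeledMask, extract_features

__all__ = [
    "TrackSet",
    "Pairing",
    "map_tracks_by_distance",
    "map_tracks_by_overlap",
    "count_tp_fp_fn",
    "jaccard",
    "alpha",
    "beta",
    "evaluate",
    "DEFAULT_EPSILON",
]

logger = logging.getLogger(__name__)

#: Default pairing tolerance (pixels), the simulated-dataset convention.
DEFAULT_EPSILON = 5.0


class TrackSet:
    """Per-track time-stamped centroid samples.

    Wraps a DataFrame with columns ``track_id, frame, row, col``; frames
    within a track are strictly increasing with at most one sample per
    (track, frame).
    """

    COLUMNS = ("track_id", "frame", "row", "col")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"track table missing columns: {sorted(missing)}")
        table = table[list(self.COLUMNS)].copy()
        table["track_id"] = table["track_id"].astype(int)
        table["frame"] = table["frame"].astype(int)
        if table.duplicated(["track_id", "frame"]).any():
            raise ValueError("duplicate (track, frame) sample")
        self.table = table.sort_values(["track_id", "frame"]).reset_index(drop=True)

    @classmethod
    def from_masks(cls, masks: Sequence[LabeledMask]) -> "TrackSet":
        """Centroid samples from globally labeled masks (track id = label)."""
        rows = []
        for mask in masks:
            feats = extract_features(mask)
            for label in feats.index:
                rows.append(
                    (
                        int(label),
                        mask.frame_index,
                        float(feats.at[label, "centroid_row"]),
                        float(feats.at[label, "centroid_col"]),
                    )
                )
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrackSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def track_ids(self) -> list[int]:
        return sorted(self.table["track_id"].unique().tolist())

    @property
    def frames(self) -> list[int]:
        return sorted(self.table["frame"].unique().tolist())

    def n_positions(self) -> int:
        return len(self.table)

    def at_frame(self, frame: int) -> pd.DataFrame:
        sub = self.table[self.table["frame"] == frame]
        return sub.set_index("track_id")[["row", "col"]]

    def links(self) -> set[tuple[int, int]]:
        """Frame-to-frame tracking decisions: (track_id, frame) such that the
        track has samples at both ``frame`` and ``frame + 1``."""
        out: set[tuple[int, int]] = set()
        for tid, sub in self.table.groupby("track_id"):
            frames = set(sub["frame"].tolist())
            out.update((int(tid), f) for f in frames if f + 1 in frames)
        return out

    def lifetime(self, track_id: int) -> list[int]:
        return self.table.loc[self.table["track_id"] == track_id, "frame"].tolist()


@dataclasses.dataclass
class Pairing:
    """Per-frame object pairing between a reference and an estimated track set.

    ``pairs[frame]`` lists ``(ref_id, est_id, distance)`` triples;
    ``track_pairs`` maps each reference track to its best-matching estimated
    track (optimal assignment on accumulated per-frame pair counts).
    """

    ref: TrackSet
    est: TrackSet
    pairs: dict[int, list[tuple[int, int, float]]]
    epsilon: float

    @property
    def track_pairs(self) -> dict[int, int]:
        counts: dict[tuple[int, int], int] = {}
        for frame_pairs in self.pairs.values():
            for r, e, _ in frame_pairs:
                counts[(r, e)] = counts.get((r, e), 0) + 1
        if not counts:
            return {}
        ref_ids = sorted({r for r, _ in counts})
        est_ids = sorted({e for _, e in counts})
        gain = np.zeros((len(ref_ids), len(est_ids)))
        for (r, e), n in counts.items():
            gain[ref_ids.index(r), est_ids.index(e)] = n
        rows, cols = linear_sum_assignment(-gain)
        return {
            ref_ids[r]: est_ids[c] for r, c in zip(rows, cols) if gain[r, c] > 0
        }

    def est_pair_at(self, ref_id: int, frame: int) -> int | None:
        for r, e, _ in self.pairs.get(frame, []):
            if r == ref_id:
                return e
        return None

    def paired_est_positions(self) -> int:
        return sum(len(v) for v in self.pairs.values())


def map_tracks_by_distance(
    ref: TrackSet, est: TrackSet, epsilon: float = DEFAULT_EPSILON
) -> Pairing:
    """Pair reference and estimated positions frame by frame.

    Within each frame an optimal one-to-one assignment minimises the total
    distance; pairs at distance >= ``epsilon`` are forbidden.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    pairs: dict[int, list[tuple[int, int, float]]] = {}
    frames = sorted(set(ref.frames) | set(est.frames))
    for frame in frames:
        r = ref.at_frame(frame)
        e = est.at_frame(frame)
        if r.empty or e.empty:
            continue
        dist = np.linalg.norm(
            r.to_numpy(float)[:, None, :] - e.to_numpy(float)[None, :, :], axis=2
        )
        gated = np.where(dist < epsilon, dist, np.inf)
        if not np.isfinite(gated).any():
            continue
        big = epsilon * (min(dist.shape) + 1)
        rows, cols = linear_sum_assignment(np.where(np.isfinite(gated), gated, big))
        frame_pairs = [
            (int(r.index[i]), int(e.index[j]), float(dist[i, j]))
            for i, j in zip(rows, cols)
            if np.isfinite(gated[i, j])
        ]
        if frame_pairs:
            pairs[frame] = frame_pairs
    return Pairing(ref, est, pairs, epsilon)


def map_tracks_by_overlap(
    ref_masks: Sequence[LabeledMask],
    est_masks: Sequence[LabeledMask],
    epsilon: float = DEFAULT_EPSILON,
) -> Pairing:
    """Pair objects by mutual maximum overlap between mask sequences.

    Two objects pair iff each is the other's unique maximum-overlap partner
    over all candidates; non-mutual pairs stay unpaired.  Paired centroid
    distances (capped at ``epsilon``) are recorded so the distance-based
    scores remain defined.
    """
    from .cost import overlap_matrix  # local import avoids a cycle

    if len(ref_masks) != len(est_masks):
        raise ValueError(
            f"frame counts differ: {len(ref_masks)} reference vs {len(est_masks)} estimated"
        )
    ref_ts = TrackSet.from_masks(ref_masks)
    est_ts = TrackSet.from_masks(est_masks)
    pairs: dict[int, list[tuple[int, int, float]]] = {}
    for rmask, emask in zip(ref_masks, est_masks):
        ov = overlap_matrix(rmask, emask)
        if len(ov) == 0:
            continue
        frame = rmask.frame_index
        rpos = ref_ts.at_frame(frame)
        epos = est_ts.at_frame(frame)
        frame_pairs = []
        for r in sorted({i for (i, _), _ in ov.items()}):
            targets = ov.targets_of(r)
            best_e = min(targets, key=lambda j: (-targets[j], j))
            if list(targets.values()).count(targets[best_e]) > 1:
                continue  # ambiguous maximum on the reference side
            sources = ov.sources_of(best_e)
            best_r = min(sources, key=lambda i: (-sources[i], i))
            if list(sources.values()).count(sources[best_r]) > 1:
                continue  # ambiguous maximum on the estimated side
            if best_r != r:
                continue
            d = float(
                np.hypot(
                    rpos.at[r, "row"] - epos.at[best_e, "row"],
                    rpos.at[r, "col"] - epos.at[best_e, "col"],
                )
            )
            frame_pairs.append((r, best_e, min(d, epsilon)))
        if frame_pairs:
            pairs[frame] = frame_pairs
    return Pairing(ref_ts, est_ts, pairs, epsilon)


def count_tp_fp_fn(pairing: Pairing, scope: str = "decisions") -> tuple[int, int, int]:
    """Count true/false positives and false negatives.

    ``scope="decisions"`` counts frame-to-frame links: an estimated link is
    a true positive when both its endpoints pair with consecutive samples of
    the same reference track.  ``scope="whole_track"`` counts entire tracks:
    an estimated track is a true positive when it pairs with one reference
    track over that reference track's complete lifetime.
    """
    ref, est = pairing.ref, pairing.est
    if scope == "decisions":
        ref_links = ref.links()
        est_links = est.links()
        tp = 0
        for est_id, frame in est_links:
            matched = False
            for r, e, _ in pairing.pairs.get(frame, []):
                if e == est_id:
                    nxt = pairing.est_pair_at(r, frame + 1)
                    matched = nxt == est_id and (r, frame) in ref_links
                    break
            tp += matched
        return tp, len(est_links) - tp, len(ref_links) - tp
    if scope == "whole_track":
        track_pairs = pairing.track_pairs
        tp_tracks = set()
        for r_id, e_id in track_pairs.items():
            if all(
                pairing.est_pair_at(r_id, frame) == e_id
                for frame in ref.lifetime(r_id)
            ):
                tp_tracks.add(e_id)
        tp = len(tp_tracks)
        fp = len(est.track_ids) - tp
        fn = len(ref.track_ids) - tp
        return tp, fp, fn
    raise ValueError(f"unknown scope {scope!r}")


def jaccard(tp: int, fp: int, fn: int) -> float:
    """TP/(TP+FN+FP); the all-zero case is defined as 1 (empty vs empty)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn == 0:
        logger.info("jaccard of empty-vs-empty defined as 1.0")
        return 1.0
    return tp / (tp + fn + fp)


def _distance_sum(pairing: Pairing) -> tuple[float, float]:
    """(D, D_dummy): summed gated distance over reference positions, where an
    unpaired reference position contributes the full tolerance ``epsilon``."""
    ref = pairing.ref
    eps = pairing.epsilon
    n_ref = ref.n_positions()
    if n_ref == 0:
        raise ValueError("reference track set is empty")
    paired_d = 0.0
    n_paired = 0
    for frame_pairs in pairing.pairs.values():
        for _, _, d in frame_pairs:
            paired_d += min(d, eps)
            n_paired += 1
    d_total = paired_d + eps * (n_ref - n_paired)
    return d_total, eps * n_ref


def alpha(pairing: Pairing) -> float:
    """Normalised closeness to the reference, ignoring false-positive tracks."""
    d, d_dummy = _distance_sum(pairing)
    return 1.0 - d / d_dummy


def beta(pairing: Pairing) -> float:
    """Like Alpha, additionally penalised by unpaired estimated positions."""
    d, d_dummy = _distance_sum(pairing)
    fp_positions = pairing.est.n_positions() - pairing.paired_est_positions()
    return (d_dummy - d) / (d_dummy + pairing.epsilon * fp_positions)


def evaluate(pairing: Pairing) -> dict[str, float]:
    """All four scores for one pairing, as a name -> value dict."""
    scores = {
        "alpha": alpha(pairing),
        "beta": beta(pairing),
        "jaccard": jaccard(*count_tp_fp_fn(pairing, "decisions")),
        "jaccard_theta": jaccard(*count_tp_fp_fn(pairing, "whole_track")),
    }
    return scores
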