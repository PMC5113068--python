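"""Pairwise overlap and weighted frame-to-frame linking costs.

Each candidate link between an object *i* at time t and an object *j* at
time t+1 is scored by three normalised terms:

* overlap: ``O_ij = |pixels(i) ∩ pixels(j)| / min(area_i, area_j)``, so full
  engulfment of the smaller object scores 1 (robust to size change during
  mitosis or collision);
* centroid displacement: ``delta_c = min(d_ij, d_max) / d_max``;
* size change: ``delta_s = |area_i - area_j| / max(area_i, area_j)``.

The linking cost is ``w_o*(1 - O) + w_c*delta_c + w_s*delta_s``; every term
lies in [0, 1], so the weights are directly comparable.  Pairs with zero
overlap whose centroids are farther apart than ``d_max`` are infeasible and
never linked.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .config import TrackingConfig
from .io import LabeledMask

__all__ = ["OverlapTable", "CostMatrix", "overlap_matrix", "linking_cost"]

INFEASIBLE = np.inf


class OverlapTable:
    """Sparse map (label_t, label_t1) -> shared pixel count (>= 1)."""

    def __init__(self, counts: dict[tuple[int, int], int]):
        self._counts = {k: int(v) for k, v in counts.items() if v > 0}

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return pair in self._counts

    def get(self, label_t: int, label_t1: int) -> int:
        return self._counts.get((label_t, label_t1), 0)

    def items(self) -> Iterable[tuple[tuple[int, int], int]]:
        return self._counts.items()

    def sources_of(self, label_t1: int) -> dict[int, int]:
        """All t-labels overlapping ``label_t1``, with pixel counts."""
        return {i: n for (i, j), n in self._counts.items() if j == label_t1}

    def targets_of(self, label_t: int) -> dict[int, int]:
        """All t+1-labels overlapping ``label_t``, with pixel counts."""
        return {j: n for (i, j), n in self._counts.items() if i == label_t}

    def restrict(self, labels_t: set[int], labels_t1: set[int]) -> "OverlapTable":
        return OverlapTable(
            {
                (i, j): n
                for (i, j), n in self._counts.items()
                if i in labels_t and j in labels_t1
            }
        )


def overlap_matrix(mask_t: LabeledMask, mask_t1: LabeledMask) -> OverlapTable:
    """Count shared pixel positions for every label pair across two frames.

    Entry (i, j) is the number of positions labeled i at t and j at t+1;
    zero-overlap pairs are omitted.
    """
    a = mask_t.pixels
    b = mask_t1.pixels
    if a.shape != b.shape:
        raise ValueError(f"frame dimensions differ: {a.shape} vs {b.shape}")
    both = (a > 0) & (b > 0)
    if not both.any():
        return OverlapTable({})
    pairs = np.stack([a[both], b[both]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return OverlapTable(
        {(int(i), int(j)): int(n) for (i, j), n in zip(uniq, counts)}
    )


@dataclasses.dataclass
class CostMatrix:
    """Dense cost matrix between objects of two consecutive frames.

    ``values[r, c]`` is the linking cost between ``labels_t[r]`` and
    ``labels_t1[c]``; infeasible pairs hold ``np.inf``.
    """

    labels_t: list[int]
    labels_t1: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.labels_t), len(self.labels_t1))
        if self.values.shape != expected:
            raise ValueError(f"cost matrix shape {self.values.shape} != {expected}")

    def cost(self, label_t: int, label_t1: int) -> float:
        return float(
            self.values[self.labels_t.index(label_t), self.labels_t1.index(label_t1)]
        )

    def is_feasible(self, label_t: int, label_t1: int) -> bool:
        return np.isfinite(self.cost(label_t, label_t1))


def linking_cost(
    feat_t: pd.DataFrame,
    feat_t1: pd.DataFrame,
    overlaps: OverlapTable,
    config: TrackingConfig,
) -> CostMatrix:
    """Build the weighted cost matrix for one frame pair.

    ``feat_t`` and ``feat_t1`` are feature tables from
    :func:`masktrack.io.extract_features`; ``overlaps`` must come from the
    same frame pair.  Labels appearing in ``overlaps`` but missing from a
    feature table are a consistency error.
    """
    for (i, j), _ in overlaps.items():
        if i not in feat_t.index:
            raise ValueError(f"overlap references label {i} missing from frame-t features")
        if j not in feat_t1.index:
            raise ValueError(f"overlap references label {j} missing from frame-t+1 features")

    labels_t = [int(x) for x in feat_t.index]
    labels_t1 = [int(x) for x in feat_t1.index]
    n, m = len(labels_t), len(labels_t1)
    values = np.full((n, m), INFEASIBLE)
    if n == 0 or m == 0:
        return CostMatrix(labels_t, labels_t1, values)

    area_t = feat_t["area"].to_numpy(float)
    area_t1 = feat_t1["area"].to_numpy(float)
    cent_t = feat_t[["centroid_row", "centroid_col"]].to_numpy(float)
    cent_t1 = feat_t1[["centroid_row", "centroid_col"]].to_numpy(float)

    dist = np.linalg.norm(cent_t[:, None, :] - cent_t1[None, :, :], axis=2)
    ov = np.zeros((n, m))
    row_of = {lab: r for r, lab in enumerate(labels_t)}
    col_of = {lab: c for c, lab in enumerate(labels_t1)}
    for (i, j), count in overlaps.items():
        ov[row_of[i], col_of[j]] = count

    min_area = np.minimum(area_t[:, None], area_t1[None, :])
    max_area = np.maximum(area_t[:, None], area_t1[None, :])
    o_term = np.clip(ov / min_area, 0.0, 1.0)
    c_term = np.minimum(dist, config.d_max) / config.d_max
    s_term = np.abs(area_t[:, None] - area_t1[None, :]) / max_area

    cost = config.w_o * (1.0 - o_term) + config.w_c * c_term + config.w_s * s_term
    feasible = (ov > 0) | (dist <= config.d_max)
    values[feasible] = cost[feasible]
    return CostMatrix(labels_t, labels_t1, values)
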