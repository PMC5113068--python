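"""Optimal one-to-one track assignment and unassigned-object classification.

After collision and mitosis handling, the remaining objects of a frame pair
are linked by minimum-cost bipartite matching (Hungarian algorithm): each
object at t shares a track with at most one object at t+1 and vice versa,
infeasible pairs are never matched, and the total cost is minimal among all
matchings of maximum feasible cardinality.

Objects left unmatched are then explained: an unassigned t object is a
mitotic mother, left the field of view through a border, or died; an
unassigned t+1 object is a daughter, entered from a border, or was born.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cost import CostMatrix
from .mitosis import MitosisEvent

__all__ = ["solve_assignment", "classify_unassigned"]


def solve_assignment(costs: CostMatrix) -> dict[int, int]:
    """Minimum-cost maximum-cardinality matching over feasible pairs.

    Returns ``{label_t: label_t1}``.  Infeasible entries are encoded as a
    large finite sentinel for the rectangular Hungarian solve and sentinel
    matches are dropped afterwards, which preserves optimality over the
    feasible pairs.  Ties between equal-cost matchings are broken by a
    lexicographic (row index, column index) preference.
    """
    values = costs.values
    n, m = values.shape
    if n == 0 or m == 0 or not np.isfinite(values).any():
        return {}

    finite_max = float(values[np.isfinite(values)].max())
    # strictly larger than any achievable matching sum
    sentinel = (finite_max + 1.0) * (min(n, m) + 1)
    padded = np.where(np.isfinite(values), values, sentinel)
    # infinitesimal lexicographic tie-break, far below real cost differences
    eps = 1.0 / (n * m + 1) * 1e-9
    tie = (np.arange(n)[:, None] * m + np.arange(m)[None, :]) * eps
    rows, cols = linear_sum_assignment(padded + tie)

    mapping: dict[int, int] = {}
    for r, c in zip(rows, cols):
        if np.isfinite(values[r, c]):
            mapping[costs.labels_t[r]] = costs.labels_t1[c]
    return mapping


def classify_unassigned(
    mapping: dict[int, int],
    feat_t: pd.DataFrame,
    feat_t1: pd.DataFrame,
    mitosis_events: list[MitosisEvent],
    *,
    consumed_t: set[int] | None = None,
    consumed_t1: set[int] | None = None,
) -> tuple[dict[int, str], dict[int, str]]:
    """Explain every object not linked by the matching.

    Returns ``(dispositions_t, dispositions_t1)``: each unassigned t label
    maps to ``mitotic_mother | left_fov | died`` and each unassigned t+1
    label to ``daughter | entered_fov | born``.  Labels in ``consumed_*``
    (already handled by collision/fusion bookkeeping) are skipped.  An
    object on the image border explains its own appearance/disappearance;
    interior objects are deaths/births.
    """
    consumed_t = consumed_t or set()
    consumed_t1 = consumed_t1 or set()
    mothers = {e.mother for e in mitosis_events}
    daughters = {d for e in mitosis_events for d in e.daughters}

    disp_t: dict[int, str] = {}
    for label in (int(x) for x in feat_t.index):
        if label in mapping or label in consumed_t:
            continue
        if label in mothers:
            disp_t[label] = "mitotic_mother"
        elif bool(feat_t.at[label, "touches_border"]):
            disp_t[label] = "left_fov"
        else:
            disp_t[label] = "died"

    assigned_t1 = set(mapping.values())
    disp_t1: dict[int, str] = {}
    for label in (int(x) for x in feat_t1.index):
        if label in assigned_t1 or label in consumed_t1:
            continue
        if label in daughters:
            disp_t1[label] = "daughter"
        elif bool(feat_t1.at[label, "touches_border"]):
            disp_t1[label] = "entered_fov"
        else:
            disp_t1[label] = "born"

    return disp_t, disp_t1
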