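"""Shared test utilities: independent oracles and mask builders."""

from __future__ import annotations

import itertools

import numpy as np

from masktrack.io import LabeledMask


def brute_force_matching(values: np.ndarray) -> tuple[int, float]:
    """Exhaustive minimum over all matchings of maximum feasible cardinality.

    ``values`` may contain ``np.inf`` for forbidden pairs.  Returns
    (cardinality, total cost).  Exponential; for instances up to ~6x6 only.
    """
    n, m = values.shape
    feasible = [
        (r, c) for r in range(n) for c in range(m) if np.isfinite(values[r, c])
    ]
    best_card = 0
    best_cost = 0.0
    for k in range(min(n, m), 0, -1):
        best_k = None
        for combo in itertools.combinations(feasible, k):
            rows = {r for r, _ in combo}
            cols = {c for _, c in combo}
            if len(rows) < k or len(cols) < k:
                continue
            total = sum(values[r, c] for r, c in combo)
            if best_k is None or total < best_k:
                best_k = total
        if best_k is not None:
            best_card, best_cost = k, best_k
            break
    return best_card, best_cost


def mask_from_array(arr, frame_index: int = 0) -> LabeledMask:
    return LabeledMask(np.asarray(arr, dtype=np.int64), frame_index)


def disk_mask(shape, centers_labels_radii, frame_index: int = 0) -> LabeledMask:
    """Paint disks (center_row, center_col, label, radius) into one mask."""
    pix = np.zeros(shape, dtype=np.int64)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r0, c0, label, radius in centers_labels_radii:
        pix[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = label
    return LabeledMask(pix, frame_index)
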