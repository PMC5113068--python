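"""Synthetic labeled-mask time-lapse sequences with known ground truth.

Two generators cover the tracker's validation scenarios:

* :func:`simulate_particles` — rigid disks under Brownian, directed or
  heading-switching motion at any density, with reflective boundaries and an
  exact reference track table;
* :func:`simulate_cells` — deformable blobs (radial low-order Fourier
  perturbations of disks, so circularity and aspect ratio are controllable)
  with Brownian centroids, scripted or random divisions that follow the four
  mitosis indicators (mother rounds up over two frames, then splits into two
  equal, similar daughters overlapping her footprint), optional genuine
  colony fusion on contact, and an optional *degraded* companion sequence in
  which touching cells are re-labeled as a single object by per-frame
  connected-component labeling — emulating collision-prone segmentation
  while the true sequence keeps them separate.

All randomness flows from one integer seed through ``numpy.random.Generator``
(PCG64, integer state), so sequences are bit-identical across runs and
platforms.  True masks carry the ground-truth track labels themselves, and
the returned lineage satisfies the lineage-graph invariants by construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import LabeledMask
from .lineage import DivisionEdge, FusionEdge, LineageGraph, Track
from .metrics import TrackSet

__all__ = ["simulate_particles", "simulate_cells", "ParticleSimulation", "CellSimulation"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


# --------------------------------------------------------------------------
# particles
# --------------------------------------------------------------------------


@dataclasses.dataclass
class ParticleSimulation:
    """Rendered particle sequence plus exact reference tracks.

    ``tracks`` holds measured (rendered-mask) centroids when masks were
    rendered, else the true continuous centers; ``true_centers`` always
    holds the continuous positions, for diffusion statistics.
    """

    masks: list[LabeledMask] | None
    tracks: TrackSet
    true_centers: TrackSet


def _reflect(pos: np.ndarray, lo: float, hi_r: float, hi_c: float) -> np.ndarray:
    """Reflect positions into [lo, hi] per axis (single-bounce adequate for
    steps much smaller than the field)."""
    out = pos.copy()
    for axis, hi in enumerate((hi_r, hi_c)):
        x = out[:, axis]
        x = np.where(x < lo, 2 * lo - x, x)
        x = np.where(x > hi, 2 * hi - x, x)
        out[:, axis] = np.clip(x, lo, hi)
    return out


def _render_disks(centers: np.ndarray, radius: float, field: tuple[int, int]) -> np.ndarray:
    pix = np.zeros(field, dtype=np.int64)
    r_int = int(np.ceil(radius))
    rr, cc = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    stamp = rr**2 + cc**2 <= radius**2
    for k, (r, c) in enumerate(centers):
        r0, c0 = int(round(r)), int(round(c))
        rows = slice(max(0, r0 - r_int), min(field[0], r0 + r_int + 1))
        cols = slice(max(0, c0 - r_int), min(field[1], c0 + r_int + 1))
        srows = slice(rows.start - (r0 - r_int), stamp.shape[0] - ((r0 + r_int + 1) - rows.stop))
        scols = slice(cols.start - (c0 - r_int), stamp.shape[1] - ((c0 + r_int + 1) - cols.stop))
        region = pix[rows, cols]
        sub = stamp[srows, scols]
        region[sub & (region == 0)] = k + 1
    return pix


def simulate_particles(
    n_particles: int,
    n_frames: int,
    motion: str = "brownian",
    step_sigma: float = 2.0,
    radius: float = 4.0,
    field: tuple[int, int] = (256, 256),
    seed: int = 0,
    *,
    directed_speed: float | None = None,
    switch_prob: float = 0.1,
    render: bool = True,
    max_placement_tries: int = 2000,
) -> ParticleSimulation:
    """Simulate disks of the given radius moving in a reflective field.

    ``motion`` selects the model: ``brownian`` (isotropic Gaussian steps of
    scale ``step_sigma`` per axis), ``directed`` (constant per-particle
    heading at ``directed_speed``, default ``2*step_sigma``, plus Gaussian
    noise) or ``switching`` (directed motion whose heading resamples with
    probability ``switch_prob`` per frame).  Initial placements are
    non-overlapping; a density too high to place raises after bounded
    retries.
    """
    if motion not in ("brownian", "directed", "switching"):
        raise ValueError(f"unknown motion model {motion!r}")
    rng = np.random.default_rng(seed)
    lo = radius + 1.0
    hi_r, hi_c = field[0] - radius - 2.0, field[1] - radius - 2.0
    if hi_r <= lo or hi_c <= lo:
        raise ValueError("particles do not fit in the field")

    centers = np.empty((0, 2))
    for _ in range(n_particles):
        for attempt in range(max_placement_tries):
            cand = np.array([rng.uniform(lo, hi_r), rng.uniform(lo, hi_c)])
            if centers.size == 0 or (
                np.linalg.norm(centers - cand, axis=1) >= 2 * radius + 1
            ).all():
                centers = np.vstack([centers, cand])
                break
        else:
            raise RuntimeError(
                f"could not place {n_particles} non-overlapping particles "
                f"of radius {radius} in field {field}"
            )

    speed = directed_speed if directed_speed is not None else 2.0 * step_sigma
    headings = rng.uniform(0, 2 * np.pi, n_particles)

    masks: list[LabeledMask] | None = [] if render else None
    rows = []
    for frame in range(n_frames):
        for k, (r, c) in enumerate(centers):
            rows.append((k + 1, frame, float(r), float(c)))
        if masks is not None:
            masks.append(LabeledMask(_render_disks(centers, radius, field), frame))
        if frame == n_frames - 1:
            break
        step = rng.normal(0.0, step_sigma, size=(n_particles, 2))
        if motion in ("directed", "switching"):
            if motion == "switching":
                flip = rng.random(n_particles) < switch_prob
                headings = np.where(flip, rng.uniform(0, 2 * np.pi, n_particles), headings)
            step += speed * np.stack([np.sin(headings), np.cos(headings)], axis=1)
        centers = _reflect(centers + step, lo, hi_r, hi_c)

    true_centers = TrackSet(pd.DataFrame(rows, columns=list(TrackSet.COLUMNS)))
    tracks = TrackSet.from_masks(masks) if masks is not None else true_centers
    return ParticleSimulation(masks, tracks, true_centers)


# --------------------------------------------------------------------------
# cells
# --------------------------------------------------------------------------


@dataclasses.dataclass
class _Lobe:
    offset: np.ndarray  # (row, col) relative to cell center
    r0: float
    amps: np.ndarray  # amplitudes of cos(k*theta + phase), k = 2, 3
    phases: np.ndarray


@dataclasses.dataclass
class _Cell:
    label: int
    center: np.ndarray
    lobes: list[_Lobe]
    division_frame: int | None = None

    @property
    def max_radius(self) -> float:
        return max(
            float(np.linalg.norm(l.offset)) + l.r0 * (1 + float(l.amps.sum()))
            for l in self.lobes
        )


def _cell_norm_distance(cell: _Cell, rr: np.ndarray, cc: np.ndarray, rounding: float) -> np.ndarray:
    """Min over lobes of (distance / R(theta)); <= 1 means inside.

    ``rounding`` in [0, 1] scales the shape perturbation down (1 = normal,
    0 = perfect disk), used to round a mother up before division.
    """
    nd = np.full(rr.shape, np.inf)
    for lobe in cell.lobes:
        dr = rr - (cell.center[0] + lobe.offset[0])
        dc = cc - (cell.center[1] + lobe.offset[1])
        dist = np.hypot(dr, dc)
        theta = np.arctan2(dr, dc)
        radial = lobe.r0 * (
            1.0
            + rounding * lobe.amps[0] * np.cos(2 * theta + lobe.phases[0])
            + rounding * lobe.amps[1] * np.cos(3 * theta + lobe.phases[1])
        )
        nd = np.minimum(nd, dist / np.maximum(radial, 1e-9))
    return nd


def _render_cells(cells: list[_Cell], field: tuple[int, int], frame: int,
                  rounding_of: dict[int, float]) -> np.ndarray:
    """Rasterize cells; contested pixels go to the relatively nearer cell."""
    pix = np.zeros(field, dtype=np.int64)
    best = np.full(field, np.inf)
    for cell in cells:
        pad = int(np.ceil(cell.max_radius)) + 2
        r0 = int(round(cell.center[0]))
        c0 = int(round(cell.center[1]))
        rows = slice(max(0, r0 - pad), min(field[0], r0 + pad + 1))
        cols = slice(max(0, c0 - pad), min(field[1], c0 + pad + 1))
        rr, cc = np.mgrid[rows, cols]
        nd = _cell_norm_distance(cell, rr, cc, rounding_of.get(cell.label, 1.0))
        inside = nd <= 1.0
        win_best = best[rows, cols]
        claim = inside & (nd < win_best)
        pix[rows, cols][claim] = cell.label
        win_best[claim] = nd[claim]
        best[rows, cols] = win_best
    return pix


@dataclasses.dataclass
class CellSimulation:
    """Cell-sheet simulation output.

    ``true_masks`` carry ground-truth track labels; ``degraded_masks`` are
    the collision-degraded companion (per-frame connected-component labels)
    when ``merge_on_contact`` was set, else identical to the true masks.
    ``merge_events`` lists ``(frame, labels merged into one degraded
    component)``.
    """

    true_masks: list[LabeledMask]
    degraded_masks: list[LabeledMask]
    lineage: LineageGraph
    tracks: TrackSet
    merge_events: list[tuple[int, frozenset[int]]]


def simulate_cells(
    n_cells: int,
    n_frames: int,
    division_rate: float = 0.0,
    fusion: bool = False,
    merge_on_contact: bool = False,
    seed: int = 0,
    *,
    field: tuple[int, int] = (256, 256),
    mean_radius: float = 12.0,
    step_sigma: float = 2.0,
    irregularity: float = 0.1,
    min_separation: float = 1.0,
    drift_to_center: float = 0.0,
    division_frames: dict[int, int] | None = None,
    max_placement_tries: int = 2000,
) -> CellSimulation:
    """Simulate deformable cells with optional divisions, fusions and
    collision-degraded segmentation.

    Cells are radial-Fourier blobs with Brownian centroids (reflective
    boundary, contact exclusion keeping centers at least ``min_separation``
    pixels beyond touching unless already closer).  ``division_rate`` is the
    per-cell per-frame division probability; ``division_frames`` scripts
    divisions as ``{initial cell index (0-based): frame}`` (the split
    appears in the following frame).  With ``fusion``, touching cells merge
    permanently into one track and a fusion edge is recorded; with
    ``merge_on_contact``, touching cells stay distinct in the true sequence
    but share one label in the degraded one.  ``drift_to_center`` adds a
    deterministic step of that many pixels per frame toward the field
    center (used to script colony-fusion scenarios).
    """
    if not 0.0 <= division_rate <= 1.0:
        raise ValueError("division_rate must be in [0, 1]")
    if fusion and merge_on_contact:
        raise ValueError("fusion and merge_on_contact are mutually exclusive")
    rng = np.random.default_rng(seed)
    division_frames = dict(division_frames or {})

    graph = LineageGraph()
    cells: list[_Cell] = []
    next_label = 1

    def new_lobe(r0: float) -> _Lobe:
        return _Lobe(
            offset=np.zeros(2),
            r0=r0,
            amps=rng.uniform(0.3 * irregularity, irregularity, size=2),
            phases=rng.uniform(0, 2 * np.pi, size=2),
        )

    # placement
    margin = mean_radius * (1 + irregularity) + 2
    for i in range(n_cells):
        r0 = mean_radius * rng.uniform(0.85, 1.15)
        for _ in range(max_placement_tries):
            cand = np.array(
                [
                    rng.uniform(margin, field[0] - margin),
                    rng.uniform(margin, field[1] - margin),
                ]
            )
            ok = all(
                np.linalg.norm(c.center - cand) >= c.max_radius + r0 * (1 + irregularity) + 4
                for c in cells
            )
            if ok:
                break
        else:
            raise RuntimeError("could not place cells without contact")
        cell = _Cell(label=next_label, center=cand, lobes=[new_lobe(r0)])
        cell.division_frame = division_frames.get(i)
        cells.append(cell)
        graph.add_track(Track(label=next_label, birth=0, death=0, origin="first_frame"))
        next_label += 1

    field_center = np.array([field[0] / 2.0, field[1] / 2.0])
    true_masks: list[LabeledMask] = []
    degraded_masks: list[LabeledMask] = []
    merge_events: list[tuple[int, frozenset[int]]] = []

    for frame in range(n_frames):
        # mother rounds up over the two frames before her split
        rounding_of = {}
        for cell in cells:
            if cell.division_frame is not None:
                lead = cell.division_frame - frame
                if lead <= 2:
                    rounding_of[cell.label] = float(np.clip(lead / 3.0, 0.0, 1.0))
        pix = _render_cells(cells, field, frame, rounding_of)
        mask = LabeledMask(pix, frame)
        true_masks.append(mask)
        for cell in cells:
            graph.tracks[cell.label].death = frame

        # degraded companion: per-frame connected components merge contacts
        if merge_on_contact:
            cc, _ = ndimage.label(pix > 0, structure=_STRUCT8)
            degraded_masks.append(LabeledMask(cc.astype(np.int64), frame))
            for comp in np.unique(cc[cc > 0]):
                members = frozenset(int(x) for x in np.unique(pix[cc == comp]) if x > 0)
                if len(members) >= 2:
                    merge_events.append((frame, members))
        else:
            degraded_masks.append(mask)

        if frame == n_frames - 1:
            break

        # fusion: touching cells merge into one track in the next frame
        if fusion and len(cells) > 1:
            merged = True
            while merged:
                merged = False
                for a_i in range(len(cells)):
                    for b_i in range(a_i + 1, len(cells)):
                        a, b = cells[a_i], cells[b_i]
                        gap = np.linalg.norm(a.center - b.center) - a.max_radius - b.max_radius
                        if gap <= 1.0:
                            area_a, area_b = a.max_radius**2, b.max_radius**2
                            w = area_a / (area_a + area_b)
                            center = w * a.center + (1 - w) * b.center
                            lobes = [
                                _Lobe(l.offset + c.center - center, l.r0, l.amps, l.phases)
                                for c in (a, b)
                                for l in c.lobes
                            ]
                            child = _Cell(label=next_label, center=center, lobes=lobes)
                            graph.add_track(
                                Track(label=next_label, birth=frame + 1,
                                      death=frame + 1, origin="fusion")
                            )
                            for parent in (a, b):
                                graph.tracks[parent.label].end = "fused"
                            graph.fusions.append(
                                FusionEdge(frozenset({a.label, b.label}), next_label, frame + 1)
                            )
                            next_label += 1
                            cells = [c for c in cells if c not in (a, b)] + [child]
                            merged = True
                            break
                    if merged:
                        break

        # divisions effective in the next frame
        new_cells: list[_Cell] = []
        for cell in list(cells):
            divide = cell.division_frame == frame
            if not divide and division_rate > 0 and cell.division_frame is None:
                divide = rng.random() < division_rate
            if not divide:
                new_cells.append(cell)
                continue
            mother = graph.tracks[cell.label]
            mother.death = frame
            mother.end = "divided"
            r_d = cell.lobes[0].r0 / np.sqrt(2.0)
            angle = rng.uniform(0, 2 * np.pi)
            axis = np.array([np.sin(angle), np.cos(angle)])
            amps = rng.uniform(0.1 * irregularity, 0.3 * irregularity, size=2)
            phases = rng.uniform(0, 2 * np.pi, size=2)
            d_labels = []
            for sign in (-1.0, 1.0):
                lobe = _Lobe(np.zeros(2), r_d, amps.copy(), phases.copy())
                daughter = _Cell(
                    label=next_label,
                    center=cell.center + sign * 0.8 * r_d * axis,
                    lobes=[lobe],
                )
                graph.add_track(
                    Track(label=next_label, birth=frame + 1, death=frame + 1,
                          origin="division")
                )
                d_labels.append(next_label)
                new_cells.append(daughter)
                next_label += 1
            graph.divisions.append(
                DivisionEdge(cell.label, (d_labels[0], d_labels[1]), frame + 1)
            )
        cells = new_cells

        # motion with contact exclusion (moving apart is always allowed)
        order = sorted(range(len(cells)), key=lambda i: cells[i].label)
        for i in order:
            cell = cells[i]
            step = rng.normal(0.0, step_sigma, size=2)
            if drift_to_center > 0:
                to_center = field_center - cell.center
                norm = np.linalg.norm(to_center)
                if norm > 1e-6:
                    step = step + drift_to_center * to_center / norm
            cand = cell.center + step
            pad = cell.max_radius + 2
            cand = np.clip(cand, pad, [field[0] - 1 - pad, field[1] - 1 - pad])
            ok = True
            for j, other in enumerate(cells):
                if j == i:
                    continue
                limit = cell.max_radius + other.max_radius + min_separation
                d_new = np.linalg.norm(cand - other.center)
                d_old = np.linalg.norm(cell.center - other.center)
                if d_new < limit and d_new < d_old:
                    ok = False
                    break
            if ok:
                cell.center = cand

    graph.validate()
    tracks = TrackSet.from_masks(true_masks)
    return CellSimulation(true_masks, degraded_masks, graph, tracks, merge_events)
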