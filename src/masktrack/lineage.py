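"""Global track construction, lineage graphs and tracking output.

The :class:`Tracker` streams over a labeled-mask sequence, runs the
per-frame-pair pipeline (overlap -> collision handling -> mitosis detection
-> Hungarian assignment -> unassigned classification) and fuses the
decisions into global tracks: every object in every frame is relabeled with
its track's unique global label, divisions become mother -> (daughter,
daughter) edges, and genuine merges become many-parents -> child fusion
edges.  Only two frames of pixel data are held at any moment, so peak memory
is independent of sequence length.

Four products completely describe the output: the globally labeled masks,
the track table (birth, death, origin, end), the division/fusion lineage,
and a per-track confidence index in [0, 1].
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

from .assignment import classify_unassigned, solve_assignment
from .collision import detect_collisions, separate_cluster
from .config import TrackingConfig
from .cost import OverlapTable, linking_cost, overlap_matrix
from .io import LabeledMask, extract_features
from .mitosis import detect_mitosis

__all__ = [
    "Track",
    "DivisionEdge",
    "FusionEdge",
    "LineageGraph",
    "Tracker",
    "TrackingResult",
    "confidence_index",
    "export_lineage",
]

#: How a track can start / stop.
ORIGINS = ("first_frame", "entered_fov", "division", "born", "fusion")
ENDS = ("last_frame", "left_fov", "died", "divided", "fused")


@dataclasses.dataclass
class Track:
    """One global track: a single object's life across frames."""

    label: int
    birth: int
    death: int
    origin: str
    end: str = "last_frame"
    max_link_cost: float = 0.0
    touched_border: bool = False
    contact_event: bool = False  # ever part of a collision split or fusion

    @property
    def lifespan(self) -> int:
        return self.death - self.birth + 1


@dataclasses.dataclass(frozen=True)
class DivisionEdge:
    mother: int
    daughters: tuple[int, int]
    frame: int  # birth frame of the daughters (mother's death + 1)


@dataclasses.dataclass(frozen=True)
class FusionEdge:
    parents: frozenset[int]
    child: int
    frame: int  # birth frame of the fused child


class LineageGraph:
    """Track records plus division and fusion edges.

    Global labels are unique positive integers; each division edge has
    exactly two daughters born at the mother's death frame + 1; the union of
    division and fusion edges, directed by time, is acyclic.
    """

    def __init__(self) -> None:
        self.tracks: dict[int, Track] = {}
        self.divisions: list[DivisionEdge] = []
        self.fusions: list[FusionEdge] = []

    def __len__(self) -> int:
        return len(self.tracks)

    def add_track(self, track: Track) -> None:
        if track.label in self.tracks:
            raise RuntimeError(f"global label {track.label} claimed twice")
        self.tracks[track.label] = track

    def to_networkx(self) -> nx.DiGraph:
        """Directed lineage: nodes are tracks, edges follow time."""
        g = nx.DiGraph()
        g.add_nodes_from(self.tracks)
        for d in self.divisions:
            g.add_edge(d.mother, d.daughters[0], kind="division", frame=d.frame)
            g.add_edge(d.mother, d.daughters[1], kind="division", frame=d.frame)
        for f in self.fusions:
            for p in sorted(f.parents):
                g.add_edge(p, f.child, kind="fusion", frame=f.frame)
        return g

    def generations(self) -> dict[int, int]:
        """Generation number per track: root tracks are generation 0 and
        each lineage edge increments by one (fusion children take the max
        over parents)."""
        g = self.to_networkx()
        gen: dict[int, int] = {}
        for label in nx.topological_sort(g):
            preds = list(g.predecessors(label))
            gen[label] = 0 if not preds else 1 + max(gen[p] for p in preds)
        return gen

    def validate(self) -> None:
        for t in self.tracks.values():
            if t.birth > t.death:
                raise AssertionError(f"track {t.label}: birth {t.birth} > death {t.death}")
            if t.origin not in ORIGINS or t.end not in ENDS:
                raise AssertionError(f"track {t.label}: bad origin/end")
        for d in self.divisions:
            mother = self.tracks[d.mother]
            if mother.end != "divided":
                raise AssertionError(f"mother {d.mother} end is {mother.end}")
            for lab in d.daughters:
                if self.tracks[lab].birth != mother.death + 1:
                    raise AssertionError(f"daughter {lab} not born at mother death + 1")
        for f in self.fusions:
            if self.tracks[f.child].birth != f.frame:
                raise AssertionError(f"fusion child {f.child} birth != edge frame")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise AssertionError("lineage contains a time-directed cycle")


def confidence_index(track: Track, graph: LineageGraph, config: TrackingConfig) -> float:
    """Average of four binary indicators of track trustworthiness.

    c1: lifespan >= ``min_track_lifespan``; c2: never touches the image
    border; c3: never involved in a collision separation or fusion; c4: no
    frame-to-frame link cost exceeded half the maximum finite cost scale.
    """
    c1 = track.lifespan >= config.min_track_lifespan
    c2 = not track.touched_border
    c3 = not track.contact_event
    c4 = track.max_link_cost <= config.max_cost / 2.0
    return (int(c1) + int(c2) + int(c3) + int(c4)) / 4.0


@dataclasses.dataclass
class TrackingResult:
    """Output of a tracking run: lineage graph, config, and (when collected)
    the globally relabeled masks."""

    graph: LineageGraph
    config: TrackingConfig
    masks: list[LabeledMask] | None = None
    n_frames: int = 0
    peak_frames_held: int = 0

    def confidence(self) -> dict[int, float]:
        return {
            lab: confidence_index(t, self.graph, self.config)
            for lab, t in sorted(self.graph.tracks.items())
        }

    def tracks_table(self) -> pd.DataFrame:
        conf = self.confidence()
        rows = [
            (t.label, t.birth, t.death, t.origin, t.end, conf[t.label])
            for t in sorted(self.graph.tracks.values(), key=lambda t: t.label)
        ]
        return pd.DataFrame(
            rows, columns=["label", "birth", "death", "origin", "end", "confidence"]
        )

    def divisions_table(self) -> pd.DataFrame:
        rows = [
            (d.mother, d.daughters[0], d.daughters[1], d.frame)
            for d in self.graph.divisions
        ]
        return pd.DataFrame(rows, columns=["mother", "daughter1", "daughter2", "frame"])

    def fusions_table(self) -> pd.DataFrame:
        rows = [
            (f.child, ";".join(str(p) for p in sorted(f.parents)), f.frame)
            for f in self.graph.fusions
        ]
        return pd.DataFrame(rows, columns=["child", "parents", "frame"])


def export_lineage(result: TrackingResult, directory: str | Path) -> dict[str, Path]:
    """Write the tracks, division and fusion tables as plain CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracks": directory / "tracks.csv",
        "divisions": directory / "divisions.csv",
        "fusions": directory / "fusions.csv",
    }
    result.tracks_table().to_csv(paths["tracks"], index=False)
    result.divisions_table().to_csv(paths["divisions"], index=False)
    result.fusions_table().to_csv(paths["fusions"], index=False)
    return paths


class Tracker:
    """Frame-to-frame tracker over labeled-mask sequences.

    Use :meth:`track` for in-memory sequences or :meth:`itertrack` to stream
    arbitrarily long sequences while holding only two frames of pixels.
    """

    def __init__(self, config: TrackingConfig | None = None):
        self.config = config or TrackingConfig()

    # -- public API ---------------------------------------------------------

    def track(self, masks: Iterable[LabeledMask]) -> TrackingResult:
        """Track a sequence and collect the relabeled masks."""
        collected: list[LabeledMask] = []
        result = self._run(masks, collect=collected)
        result.masks = collected
        return result

    def itertrack(
        self, masks: Iterable[LabeledMask]
    ) -> Iterator[LabeledMask | TrackingResult]:
        """Yield globally relabeled frames one at a time; the final item is
        the :class:`TrackingResult` (with ``masks=None``)."""

        def stream() -> Iterator[LabeledMask | TrackingResult]:
            result = yield from self._generate(masks)
            yield result

        return stream()

    # -- pipeline -----------------------------------------------------------

    def _run(self, masks: Iterable[LabeledMask], collect: list[LabeledMask]) -> TrackingResult:
        gen = self._generate(masks)
        while True:
            try:
                collect.append(next(gen))
            except StopIteration as stop:
                return stop.value

    def _generate(self, masks: Iterable[LabeledMask]):
        cfg = self.config
        graph = LineageGraph()
        frames_held = 0
        peak_held = 0
        next_label = 1

        def acquire() -> None:
            nonlocal frames_held, peak_held
            frames_held += 1
            peak_held = max(peak_held, frames_held)

        def release() -> None:
            nonlocal frames_held
            frames_held -= 1

        it = iter(masks)
        try:
            first = next(it)
        except StopIteration:
            raise ValueError("empty mask sequence") from None
        acquire()

        # frame 0: every object starts a track
        feat_prev = extract_features(first)
        relabel = {}
        for raw in sorted(int(x) for x in feat_prev.index):
            relabel[raw] = next_label
            graph.add_track(
                Track(
                    label=next_label,
                    birth=0,
                    death=0,
                    origin="first_frame",
                    touched_border=bool(feat_prev.at[raw, "touches_border"]),
                )
            )
            next_label += 1
        prev = self._apply_relabel(first, relabel)
        feat_prev = feat_prev.rename(index=relabel)
        yield prev

        n_frames = 1
        for cur in it:
            acquire()
            if cur.pixels.shape != prev.pixels.shape:
                raise ValueError(
                    f"frame {cur.frame_index}: shape {cur.pixels.shape} != {prev.pixels.shape}"
                )
            t = prev.frame_index
            feat_cur = extract_features(cur)
            overlaps = overlap_matrix(prev, cur)

            consumed_prev: set[int] = set()
            consumed_cur: set[int] = set()
            direct_links: dict[int, int] = {}  # prev global -> cur label
            contact_prev: set[int] = set()
            contact_cur: set[int] = set()
            fusion_specs: list[tuple[frozenset[int], int]] = []

            # 1. collision / fusion handling
            events = detect_collisions(overlaps, feat_prev, feat_cur, cfg)
            if events and not cfg.enable_fusion:
                for event in sorted(events, key=lambda e: e.cluster):
                    cur, part_of = separate_cluster(prev, cur, event)
                    for src, part in part_of.items():
                        direct_links[src] = part
                        contact_prev.add(src)
                        contact_cur.add(part)
                # mask changed: refresh geometry and overlaps
                feat_cur = extract_features(cur)
                overlaps = overlap_matrix(prev, cur)
                consumed_prev |= set(direct_links)
                consumed_cur |= set(direct_links.values())
            elif events:
                for event in sorted(events, key=lambda e: e.cluster):
                    fusion_specs.append((event.sources, event.cluster))
                    consumed_prev |= event.sources
                    consumed_cur.add(event.cluster)
                    contact_prev |= event.sources
                    contact_cur.add(event.cluster)

            # 2. mitosis detection on the remaining objects
            remaining_prev = set(map(int, feat_prev.index)) - consumed_prev
            remaining_cur = set(map(int, feat_cur.index)) - consumed_cur
            mito = detect_mitosis(
                feat_prev.loc[sorted(remaining_prev)],
                feat_cur.loc[sorted(remaining_cur)],
                overlaps.restrict(remaining_prev, remaining_cur),
                cfg,
            )
            mothers = {e.mother for e in mito}
            daughters = {d for e in mito for d in e.daughters}

            # 3. Hungarian assignment over what is left
            free_prev = sorted(remaining_prev - mothers)
            free_cur = sorted(remaining_cur - daughters)
            costs = linking_cost(
                feat_prev.loc[free_prev],
                feat_cur.loc[free_cur],
                overlaps.restrict(set(free_prev), set(free_cur)),
                cfg,
            )
            mapping = solve_assignment(costs)

            # 4. classify everything unmatched
            disp_prev, disp_cur = classify_unassigned(
                mapping,
                feat_prev,
                feat_cur,
                mito,
                consumed_t=consumed_prev,
                consumed_t1=consumed_cur,
            )

            # 5. fuse the decisions into the graph and a relabeling map
            relabel = {}
            for g_label, cur_label in sorted(mapping.items()):
                track = graph.tracks[g_label]
                track.death = t + 1
                track.max_link_cost = max(
                    track.max_link_cost, costs.cost(g_label, cur_label)
                )
                relabel[cur_label] = g_label
            for g_label, cur_label in sorted(direct_links.items()):
                track = graph.tracks[g_label]
                track.death = t + 1
                track.contact_event = True
                relabel[cur_label] = g_label

            for g_label, disposition in sorted(disp_prev.items()):
                track = graph.tracks[g_label]
                if disposition == "mitotic_mother":
                    track.end = "divided"
                elif disposition == "left_fov":
                    track.end = "left_fov"
                else:
                    track.end = "died"

            # new tracks: daughters, fusion children, entrants, births —
            # fresh labels in ascending current-frame label order
            origin_of: dict[int, str] = {}
            for parents, cluster in fusion_specs:
                origin_of[cluster] = "fusion"
                for p in parents:
                    parent = graph.tracks[p]
                    parent.end = "fused"
                    parent.contact_event = True
            for cur_label, disposition in disp_cur.items():
                origin_of[cur_label] = (
                    "division"
                    if disposition == "daughter"
                    else "entered_fov"
                    if disposition == "entered_fov"
                    else "born"
                )
            fresh: dict[int, int] = {}
            for cur_label in sorted(origin_of):
                fresh[cur_label] = next_label
                graph.add_track(
                    Track(
                        label=next_label,
                        birth=t + 1,
                        death=t + 1,
                        origin=origin_of[cur_label],
                        contact_event=cur_label in contact_cur,
                    )
                )
                relabel[cur_label] = next_label
                next_label += 1

            for e in mito:
                graph.divisions.append(
                    DivisionEdge(
                        e.mother,
                        (fresh[e.daughters[0]], fresh[e.daughters[1]]),
                        t + 1,
                    )
                )
            for parents, cluster in fusion_specs:
                graph.fusions.append(FusionEdge(parents, fresh[cluster], t + 1))

            claimed = set(relabel)
            present = set(map(int, feat_cur.index))
            if claimed != present:
                raise RuntimeError(
                    f"frame {t + 1}: objects {sorted(present ^ claimed)} claimed "
                    "zero or multiple times"
                )

            new_prev = self._apply_relabel(cur, relabel)
            feat_prev = feat_cur.rename(index=relabel)
            for g_label in map(int, feat_prev.index):
                if bool(feat_prev.at[g_label, "touches_border"]):
                    graph.tracks[g_label].touched_border = True

            release()  # old prev pixels dropped here
            prev = new_prev
            del cur, new_prev
            n_frames += 1
            yield prev

        release()
        graph.validate()
        return TrackingResult(
            graph=graph,
            config=cfg,
            masks=None,
            n_frames=n_frames,
            peak_frames_held=peak_held,
        )

    @staticmethod
    def _apply_relabel(mask: LabeledMask, relabel: dict[int, int]) -> LabeledMask:
        pix = mask.pixels
        if not relabel:
            return LabeledMask(np.zeros_like(pix), mask.frame_index)
        lut = np.zeros(int(pix.max()) + 1, dtype=np.int64)
        for old, new in relabel.items():
            lut[old] = new
        return LabeledMask(lut[pix], mask.frame_index)
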