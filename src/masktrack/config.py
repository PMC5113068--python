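"""Tracking configuration.

All tunable parameters of the tracking pipeline live in a single flat
:class:`TrackingConfig`.  The three cost weights trade off the evidence used
for frame-to-frame linking (overlap, centroid displacement, size change); the
remaining thresholds gate the collision and mitosis detectors.  A config can
be loaded from a flat JSON file whose keys mirror the field names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path


@dataclasses.dataclass
class TrackingConfig:
    """Parameters of the tracking pipeline.

    Parameters
    ----------
    w_o, w_c, w_s : float
        Non-negative weights of the overlap, centroid-distance and
        size-change cost terms.  Each term is normalised to [0, 1], so the
        weights are directly comparable.  At least one must be positive.
    d_max : float
        Maximum plausible centroid displacement per frame, in pixels.
        Pairs with zero overlap and displacement beyond ``d_max`` are
        infeasible links.
    min_division_overlap : float
        Minimum overlap fraction used by the mitosis detector, both per
        daughter (fraction of the daughter's area covered by the mother)
        and combined (fraction of the mother's area covered by the two
        daughters together).
    min_mother_circularity : float
        Minimum circularity of the mother in the frame before division.
    min_daughter_size_similarity : float
        Minimum min/max area ratio of the daughter pair.
    min_daughter_aspect_similarity : float
        Minimum min/max aspect-ratio ratio of the daughter pair.
    enable_fusion : bool
        When true, merged objects are treated as genuine fusions (colony
        tracking): masks are never split and a fusion edge is recorded.
        When false, merges are treated as segmentation collisions and the
        cluster is split back into its sources.
    min_collision_overlap : float
        Fraction of a source object's own area that must fall inside a
        candidate cluster for the source to count as a collision parent.
    min_track_lifespan : int
        Minimum length (frames) for a track to earn the lifespan point of
        its confidence index.
    seed : int
        Random seed, used only by the simulator.
    """

    w_o: float = 1.0
    w_c: float = 0.5
    w_s: float = 0.2
    d_max: float = 50.0
    min_division_overlap: float = 0.2
    min_mother_circularity: float = 0.3
    min_daughter_size_similarity: float = 0.5
    min_daughter_aspect_similarity: float = 0.7
    enable_fusion: bool = False
    min_collision_overlap: float = 0.5
    min_track_lifespan: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.w_o, self.w_c, self.w_s) < 0:
            raise ValueError("cost weights must be non-negative")
        if self.w_o + self.w_c + self.w_s <= 0:
            raise ValueError("at least one cost weight must be positive")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        for name in (
            "min_division_overlap",
            "min_mother_circularity",
            "min_daughter_size_similarity",
            "min_daughter_aspect_similarity",
            "min_collision_overlap",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_track_lifespan < 1:
            raise ValueError("min_track_lifespan must be >= 1")

    @property
    def max_cost(self) -> float:
        """Largest finite linking cost, ``w_o + w_c + w_s``."""
        return self.w_o + self.w_c + self.w_s

    @classmethod
    def from_json(cls, path: str | Path) -> "TrackingConfig":
        """Load a config from a flat JSON file; unknown keys are rejected."""
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    def replace(self, **changes) -> "TrackingConfig":
        return dataclasses.replace(self, **changes)
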