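"""Environment geometry: distances from a location to boundaries and objects.

Environments are the simplified arenas used in rodent place-cell experiments:
rectangular tracks / open boxes and an annular ("circular") track carrying
discrete objects and a passage-blocking barrier.  All coordinates are in cm,
Cartesian origin at the south-west corner, x increasing eastward and y
northward.  The 1D coordinate on the circular track is arc length along the
track midline, measured counter-clockwise from the barrier.

Each distance is returned as an :class:`ObservationGeometry` carrying the
scalar distance and, where meaningful, the unit direction along which the
observation constrains position.  These distances feed the observation model
of :mod:`placefields.cue_model` (observation noise grows linearly with
distance, cf. Weber's law).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Point2D",
    "RectEnvironment",
    "CircularTrack",
    "ObservationGeometry",
    "rect_boundary_distances",
    "track_distances",
    "validate_environment",
    "environment_from_json",
    "environment_to_json",
]


@dataclass(frozen=True)
class Point2D:
    """A location in the environment, in cm."""

    x_cm: float
    y_cm: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_cm) and math.isfinite(self.y_cm)):
            raise ValueError("Point2D coordinates must be finite")


@dataclass(frozen=True)
class RectEnvironment:
    """A rectangular arena (track or open box): length along x, width along y."""

    length_cm: float
    width_cm: float

    def __post_init__(self) -> None:
        validate_environment(self)

    def contains(self, p: Point2D) -> bool:
        return 0.0 <= p.x_cm <= self.length_cm and 0.0 <= p.y_cm <= self.width_cm


@dataclass(frozen=True)
class CircularTrack:
    """An annular track with objects and a barrier.

    The 1D coordinate is arc length (cm) along the track midline, counter-
    clockwise from the barrier, so the barrier sits at arc 0 (equivalently at
    the circumference).  ``barrier_arc_cm`` may be nonzero for tracks described
    in another reference frame; distances only depend on arc differences.
    """

    diameter_cm: float
    track_width_cm: float
    barrier_arc_cm: float = 0.0
    object_arcs_cm: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "object_arcs_cm", tuple(float(a) for a in self.object_arcs_cm))
        validate_environment(self)

    @property
    def circumference_cm(self) -> float:
        return math.pi * self.diameter_cm


@dataclass(frozen=True)
class ObservationGeometry:
    """A single distance observation: how far, and along which direction."""

    distance_cm: float
    normal: tuple[float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.distance_cm < 0:
            raise ValueError(f"distance_cm must be >= 0, got {self.distance_cm}")
        if self.normal is not None:
            n = np.asarray(self.normal, dtype=float)
            if n.shape != (2,) or not np.isclose(np.linalg.norm(n), 1.0):
                raise ValueError("normal must be a unit 2-vector")
            object.__setattr__(self, "normal", (float(n[0]), float(n[1])))


def validate_environment(env):
    """Check an environment's type invariants; return it unchanged if valid."""
    if isinstance(env, RectEnvironment):
        if not env.length_cm > 0:
            raise ValueError(f"length_cm must be > 0, got {env.length_cm}")
        if not env.width_cm > 0:
            raise ValueError(f"width_cm must be > 0, got {env.width_cm}")
        return env
    if isinstance(env, CircularTrack):
        if not env.diameter_cm > 0:
            raise ValueError(f"diameter_cm must be > 0, got {env.diameter_cm}")
        if not env.track_width_cm > 0:
            raise ValueError(f"track_width_cm must be > 0, got {env.track_width_cm}")
        circ = math.pi * env.diameter_cm
        for name, arc in [("barrier_arc_cm", env.barrier_arc_cm)] + [
            ("object_arcs_cm", a) for a in env.object_arcs_cm
        ]:
            if not (0.0 <= arc < circ):
                raise ValueError(
                    f"{name} arc {arc} outside [0, circumference={circ:.4f})"
                )
        return env
    raise TypeError(f"unknown environment type: {type(env).__name__}")


def rect_boundary_distances(p: Point2D, env: RectEnvironment) -> list[ObservationGeometry]:
    """Distances from ``p`` to the four walls (W, E, S, N order).

    Each entry carries the inward-pointing wall normal, i.e. the direction
    along which that wall constrains position.  Opposing distances sum to the
    corresponding extent.
    """
    if not 0.0 <= p.x_cm <= env.length_cm:
        raise ValueError(f"x={p.x_cm} outside [0, L={env.length_cm}]")
    if not 0.0 <= p.y_cm <= env.width_cm:
        raise ValueError(f"y={p.y_cm} outside [0, W={env.width_cm}]")
    return [
        ObservationGeometry(p.x_cm, (1.0, 0.0), "west"),
        ObservationGeometry(env.length_cm - p.x_cm, (-1.0, 0.0), "east"),
        ObservationGeometry(p.y_cm, (0.0, 1.0), "south"),
        ObservationGeometry(env.width_cm - p.y_cm, (0.0, -1.0), "north"),
    ]


def _path_distance(s: float, a: float, circ: float) -> float:
    """Path length along the track from arc s to arc a without crossing arc 0.

    Arc 0 is the barrier, which blocks passage, so the path is simply the
    absolute arc difference: both points live on the same barrier-cut interval
    [0, circ).
    """
    return abs(s - a)


def track_distances(s_cm: float, track: CircularTrack) -> list[ObservationGeometry]:
    """Distances along the track from arc position ``s_cm`` to each object and the barrier.

    Paths never cross the barrier (it blocks passage), so object distances are
    plain arc differences in the barrier-cut coordinate.  The barrier itself is
    reachable from either side; its distance is the min of the two approaches.
    Entries are one per object (in listed order) plus a final ``"barrier"`` entry.
    """
    circ = track.circumference_cm
    if not 0.0 <= s_cm < circ:
        raise ValueError(f"arc position {s_cm} outside [0, circumference={circ:.4f})")
    out = [
        ObservationGeometry(_path_distance(s_cm, a, circ), label=f"object_{i}")
        for i, a in enumerate(track.object_arcs_cm)
    ]
    out.append(ObservationGeometry(min(s_cm, circ - s_cm), label="barrier"))
    return out


# ---------------------------------------------------------------------------
# JSON environment configs


def environment_from_json(obj) -> RectEnvironment | CircularTrack:
    """Build an environment from a JSON dict / string / path-like config.

    Rect: ``{"type": "rect", "length_cm": L, "width_cm": W}``.
    Circular: ``{"type": "circular_track", "diameter_cm": D, "track_width_cm": w,
    "barrier": arc, "objects": [arcs...]}``.  All units cm.
    """
    if isinstance(obj, (str, bytes)):
        obj = json.loads(obj)
    elif hasattr(obj, "read"):
        obj = json.load(obj)
    kind = obj.get("type")
    if kind == "rect":
        return RectEnvironment(float(obj["length_cm"]), float(obj["width_cm"]))
    if kind == "circular_track":
        return CircularTrack(
            diameter_cm=float(obj["diameter_cm"]),
            track_width_cm=float(obj["track_width_cm"]),
            barrier_arc_cm=float(obj.get("barrier", 0.0)),
            object_arcs_cm=tuple(float(a) for a in obj.get("objects", ())),
        )
    raise ValueError(f"unknown environment type: {kind!r}")


def environment_to_json(env) -> dict:
    if isinstance(env, RectEnvironment):
        return {"type": "rect", "length_cm": env.length_cm, "width_cm": env.width_cm}
    if isinstance(env, CircularTrack):
        return {
            "type": "circular_track",
            "diameter_cm": env.diameter_cm,
            "track_width_cm": env.track_width_cm,
            "barrier": env.barrier_arc_cm,
            "objects": list(env.object_arcs_cm),
        }
    raise TypeError(f"unknown environment type: {type(env).__name__}")
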