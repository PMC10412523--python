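"""Domain types for change-detection-while-driving sessions.

A session couples four time-aligned streams recorded while a participant
drives a fixed route through three visuospatial-complexity zones (low,
medium, high), encountering scheduled "changes" (sudden behaviour changes of
street users, or property changes of static objects) that they report with
two buttons:

* a gaze stream — unit gaze directions plus head position, nominal 120 Hz;
* a driving stream — speed (km/h) and a boolean brake-pedal signal;
* button presses — right marks behaviour changes, left property changes;
* the change-event schedule and the time-indexed areas of interest (AOIs)
  each change is anchored to.

Conventions used throughout the package:

* world frame is right-handed with coordinates in metres; gaze is a unit
  direction from ``head_pos``;
* timestamps are seconds from session start; every window is half-open
  ``[a, b)`` so that a sample or press exactly at an edge belongs to the
  later window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ValidationError",
    "SessionFormatError",
    "ChangeType",
    "Complexity",
    "Side",
    "GAP_LEVELS_S",
    "COMPLEXITY_LEVELS",
    "CHANGE_TYPES",
    "GROUP_ORDERS",
    "SIDE_FOR_TYPE",
    "GazeStream",
    "DrivingStream",
    "ButtonPress",
    "AOI",
    "ChangeEvent",
    "SessionLog",
]


class ValidationError(ValueError):
    """An in-memory record violates a structural invariant."""


class SessionFormatError(ValueError):
    """A session directory is missing files or contains malformed ones."""


ChangeType = Literal["behaviour_relevant", "behaviour_irrelevant", "property"]
Complexity = Literal["low", "medium", "high"]
Side = Literal["left", "right"]

GAP_LEVELS_S: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)
COMPLEXITY_LEVELS: tuple[str, ...] = ("low", "medium", "high")
CHANGE_TYPES: tuple[str, ...] = ("behaviour_relevant", "behaviour_irrelevant", "property")

#: Complexity-block order each counterbalancing group drives through.
GROUP_ORDERS: dict[str, tuple[str, str, str]] = {
    "A": ("medium", "high", "low"),
    "B": ("high", "low", "medium"),
    "C": ("low", "medium", "high"),
}

#: Fixed button mapping: right marks behaviour changes, left property changes.
SIDE_FOR_TYPE: dict[str, str] = {
    "behaviour_relevant": "right",
    "behaviour_irrelevant": "right",
    "property": "left",
}

_SPEED_LIMIT_KMH = 30.0
_SPEED_TOL_KMH = 2.0
_UNIT_TOL = 1e-6


def _check_strictly_increasing(t: np.ndarray, what: str) -> None:
    if t.size >= 2:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"{what}: timestamps not strictly increasing at record {i + 1} "
                f"(t[{i}]={t[i]!r}, t[{i + 1}]={t[i + 1]!r})"
            )


@dataclass
class GazeStream:
    """Array-backed sequence of gaze samples.

    Attributes
    ----------
    t : (n,) seconds from session start, strictly increasing.
    gaze_dir : (n, 3) unit gaze directions in the world frame.
    head_pos : (n, 3) head positions, metres.
    valid : (n,) bool; invalid samples (blinks, tracking loss) carry no
        usable direction and break fixation windows downstream.
    """

    t: np.ndarray
    gaze_dir: np.ndarray
    head_pos: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gaze_dir = np.asarray(self.gaze_dir, dtype=float).reshape(-1, 3)
        self.head_pos = np.asarray(self.head_pos, dtype=float).reshape(-1, 3)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return self.t.size

    def validate(self) -> None:
        n = len(self)
        if not (self.gaze_dir.shape[0] == self.head_pos.shape[0] == self.valid.size == n):
            raise ValidationError("gaze stream: column lengths differ")
        _check_strictly_increasing(self.t, "gaze stream")
        if n:
            norms = np.linalg.norm(self.gaze_dir[self.valid], axis=1)
            bad = np.nonzero(np.abs(norms - 1.0) > _UNIT_TOL)[0]
            if bad.size:
                idx = int(np.nonzero(self.valid)[0][bad[0]])
                raise ValidationError(
                    f"gaze stream: gaze_dir at record {idx} is not a unit vector "
                    f"(norm={norms[bad[0]]:.6g})"
                )


@dataclass
class DrivingStream:
    """Telemetry samples: speed in km/h and the boolean brake-pedal signal."""

    t: np.ndarray
    speed_kmh: np.ndarray
    brake: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.speed_kmh = np.asarray(self.speed_kmh, dtype=float)
        self.brake = np.asarray(self.brake, dtype=bool)

    def __len__(self) -> int:
        return self.t.size

    def validate(self, speed_limit_kmh: float = _SPEED_LIMIT_KMH) -> None:
        if not (self.speed_kmh.size == self.brake.size == self.t.size):
            raise ValidationError("driving stream: column lengths differ")
        _check_strictly_increasing(self.t, "driving stream")
        if self.t.size:
            if float(self.speed_kmh.min(initial=0.0)) < 0.0:
                i = int(np.nonzero(self.speed_kmh < 0)[0][0])
                raise ValidationError(f"driving stream: negative speed at record {i}")
            cap = speed_limit_kmh + _SPEED_TOL_KMH
            over = np.nonzero(self.speed_kmh > cap)[0]
            if over.size:
                i = int(over[0])
                raise ValidationError(
                    f"driving stream: speed {self.speed_kmh[i]:.2f} km/h at record {i} "
                    f"exceeds limit {speed_limit_kmh} km/h (+{_SPEED_TOL_KMH} tolerance)"
                )


@dataclass(frozen=True)
class ButtonPress:
    """A single response: right marks behaviour changes, left property changes."""

    t: float
    side: Side

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"press side must be 'left' or 'right', got {self.side!r}")


@dataclass
class AOI:
    """Time-indexed spherical area of interest around an agent or object.

    ``track`` gives the AOI centre along time; the centre at an arbitrary
    instant is linearly interpolated. A fixation "lands" on the AOI when the
    angle between its centroid direction and the head-to-centre direction is
    at most ``arctan(radius / distance)``.
    """

    aoi_id: str
    kind: Literal["agent", "object"]
    track_t: np.ndarray
    track_center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.track_t = np.asarray(self.track_t, dtype=float)
        self.track_center = np.asarray(self.track_center, dtype=float).reshape(-1, 3)

    def validate(self) -> None:
        if self.kind not in ("agent", "object"):
            raise ValidationError(f"AOI {self.aoi_id}: kind must be agent|object, got {self.kind!r}")
        if self.radius <= 0:
            raise ValidationError(f"AOI {self.aoi_id}: radius must be > 0")
        if self.track_t.size != self.track_center.shape[0]:
            raise ValidationError(f"AOI {self.aoi_id}: track lengths differ")
        if self.track_t.size < 2:
            raise ValidationError(f"AOI {self.aoi_id}: track needs at least 2 samples")
        _check_strictly_increasing(self.track_t, f"AOI {self.aoi_id} track")

    def covers(self, t0: float, t1: float) -> bool:
        return bool(self.track_t[0] <= t0 and self.track_t[-1] >= t1)

    def center_at(self, t: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated AOI centre at time ``t`` (must be covered)."""
        t = np.asarray(t, dtype=float)
        out = np.empty(t.shape + (3,))
        for k in range(3):
            out[..., k] = np.interp(t, self.track_t, self.track_center[:, k])
        return out


@dataclass(frozen=True)
class ChangeEvent:
    """One scheduled change and the pair/gap structure it belongs to.

    Changes come in pairs: a behaviour change (relevant or irrelevant to the
    driving task) followed, after ``gap_s`` seconds, by a property change of
    a nearby static object. ``gap_s`` is stored on both members of a pair;
    it is defined as the property-change delay after the paired behaviour
    change. ``encounter_index`` is the 0-based ordinal position of the
    change in the session.
    """

    change_id: str
    pair_id: str
    change_type: ChangeType
    complexity: Complexity
    trigger_t: float
    aoi_id: str
    gap_s: float
    encounter_index: int

    def __post_init__(self) -> None:
        if self.change_type not in CHANGE_TYPES:
            raise ValidationError(f"change {self.change_id}: bad change_type {self.change_type!r}")
        if self.complexity not in COMPLEXITY_LEVELS:
            raise ValidationError(f"change {self.change_id}: bad complexity {self.complexity!r}")
        if self.gap_s not in GAP_LEVELS_S:
            raise ValidationError(
                f"change {self.change_id}: gap_s {self.gap_s!r} not one of {GAP_LEVELS_S}"
            )

    @property
    def required_side(self) -> str:
        return SIDE_FOR_TYPE[self.change_type]

    @property
    def is_behaviour(self) -> bool:
        return self.change_type != "property"


@dataclass
class SessionLog:
    """Everything recorded for one participant, plus the schedule metadata.

    ``segment_bounds`` maps each complexity level to its half-open time
    interval ``[a, b)``; the three intervals partition the session and their
    order along time matches the group's block order.
    """

    participant_id: str
    group: Literal["A", "B", "C"]
    gaze: GazeStream
    driving: DrivingStream
    presses: list[ButtonPress]
    events: list[ChangeEvent]
    aois: dict[str, AOI]
    segment_bounds: dict[str, tuple[float, float]]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.group not in GROUP_ORDERS:
            raise ValidationError(f"group must be one of A,B,C, got {self.group!r}")
        self.gaze.validate()
        self.driving.validate()
        for i in range(1, len(self.presses)):
            if self.presses[i].t <= self.presses[i - 1].t:
                raise ValidationError(f"presses: timestamps not strictly increasing at record {i}")
        for aoi in self.aois.values():
            aoi.validate()
        for ev in self.events:
            if ev.aoi_id not in self.aois:
                raise ValidationError(
                    f"change {ev.change_id}: unknown aoi_id {ev.aoi_id!r}"
                )
        self._validate_pairs()
        self._validate_segments()

    def _validate_pairs(self) -> None:
        by_pair: dict[str, list[ChangeEvent]] = {}
        for ev in self.events:
            by_pair.setdefault(ev.pair_id, []).append(ev)
        for pair_id, members in by_pair.items():
            if len(members) != 2:
                raise ValidationError(f"pair {pair_id}: expected 2 changes, found {len(members)}")
            beh = [e for e in members if e.is_behaviour]
            prop = [e for e in members if not e.is_behaviour]
            if len(beh) != 1 or len(prop) != 1:
                raise ValidationError(
                    f"pair {pair_id}: needs exactly one behaviour and one property change"
                )
            b, p = beh[0], prop[0]
            if b.trigger_t > p.trigger_t:
                raise ValidationError(f"pair {pair_id}: behaviour change must trigger first")
            if abs((p.trigger_t - b.trigger_t) - p.gap_s) > 1e-9:
                raise ValidationError(
                    f"pair {pair_id}: trigger spacing {p.trigger_t - b.trigger_t:.6g} s "
                    f"does not equal gap_s {p.gap_s:.6g} s"
                )

    def _validate_segments(self) -> None:
        if set(self.segment_bounds) != set(COMPLEXITY_LEVELS):
            raise ValidationError("segment_bounds must name exactly low, medium, high")
        order = GROUP_ORDERS[self.group]
        bounds = [self.segment_bounds[level] for level in order]
        for (a, b) in bounds:
            if not a < b:
                raise ValidationError("segment_bounds: empty or inverted interval")
        for (_, prev_end), (start, _) in zip(bounds, bounds[1:]):
            if abs(prev_end - start) > 1e-9:
                raise ValidationError(
                    "segment_bounds: segments must be contiguous in the group's block order"
                )
        for ev in self.events:
            a, b = self.segment_bounds[ev.complexity]
            if not (a <= ev.trigger_t < b):
                raise ValidationError(
                    f"change {ev.change_id}: trigger {ev.trigger_t:.6g} s outside its "
                    f"{ev.complexity} segment [{a:.6g}, {b:.6g})"
                )

    def events_sorted(self) -> list[ChangeEvent]:
        """Events in encounter order (trigger time; behaviour first at ties)."""
        return sorted(self.events, key=lambda e: (e.trigger_t, 0 if e.is_behaviour else 1))

    def complexity_at(self, t: float) -> str | None:
        for level, (a, b) in self.segment_bounds.items():
            if a <= t < b:
                return level
        return None
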