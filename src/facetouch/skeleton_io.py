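"""Skeleton data model and file I/O.

The pipeline consumes time-stamped 3D body-tracking skeletons of the kind
emitted by consumer depth-camera body trackers: one hierarchical skeleton of
32 named joints per tracked body per frame, with positions in millimeters in
a right-handed camera space (x right, y down, z away from the sensor).

Two on-disk dialects are supported for skeleton streams (JSON-lines and a
long-format CSV), plus CSV dialects for contact-event records and per-frame
label tables.  Serialization is deterministic: positions are written with a
fixed precision of 0.001 mm and timestamps with microsecond precision, so
writing the same frames twice produces identical bytes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np

__all__ = [
    "JointName",
    "Joint",
    "SkeletonFrame",
    "EventRecord",
    "FrameLabel",
    "EVENT_LABELS",
    "CONTACT_AREAS",
    "ParseError",
    "ValidationError",
    "read_skeleton_stream",
    "write_skeleton_stream",
    "read_events",
    "write_events",
    "read_frame_labels",
    "write_frame_labels",
]


class ParseError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Structurally parseable data violates a domain invariant."""


class JointName(str, Enum):
    """The 32 joints of the Azure-Kinect-style body-tracking skeleton."""

    PELVIS = "pelvis"
    SPINE_NAVEL = "spine_navel"
    SPINE_CHEST = "spine_chest"
    NECK = "neck"
    CLAVICLE_LEFT = "clavicle_left"
    SHOULDER_LEFT = "shoulder_left"
    ELBOW_LEFT = "elbow_left"
    WRIST_LEFT = "wrist_left"
    HAND_LEFT = "hand_left"
    HANDTIP_LEFT = "handtip_left"
    THUMB_LEFT = "thumb_left"
    CLAVICLE_RIGHT = "clavicle_right"
    SHOULDER_RIGHT = "shoulder_right"
    ELBOW_RIGHT = "elbow_right"
    WRIST_RIGHT = "wrist_right"
    HAND_RIGHT = "hand_right"
    HANDTIP_RIGHT = "handtip_right"
    THUMB_RIGHT = "thumb_right"
    HIP_LEFT = "hip_left"
    KNEE_LEFT = "knee_left"
    ANKLE_LEFT = "ankle_left"
    FOOT_LEFT = "foot_left"
    HIP_RIGHT = "hip_right"
    KNEE_RIGHT = "knee_right"
    ANKLE_RIGHT = "ankle_right"
    FOOT_RIGHT = "foot_right"
    HEAD = "head"
    NOSE = "nose"
    EYE_LEFT = "eye_left"
    EAR_LEFT = "ear_left"
    EYE_RIGHT = "eye_right"
    EAR_RIGHT = "ear_right"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Canonical serialization order (enum definition order).
_JOINT_ORDER: tuple[JointName, ...] = tuple(JointName)
_JOINT_BY_NAME: dict[str, JointName] = {j.value: j for j in JointName}

#: Six contact-area classes emitted by the classifier.
CONTACT_AREAS: tuple[str, ...] = (
    "mouth_nose",
    "right_eye",
    "left_eye",
    "right_ear",
    "left_ear",
    "low_risk",
)

#: Closed event-label vocabulary: the six contact classes, plus ``occlusion``
#: (truth annotations of face-hiding gestures without contact) and
#: ``no_detection`` (a truth event the classifier missed during matching).
EVENT_LABELS: tuple[str, ...] = CONTACT_AREAS + ("occlusion", "no_detection")


@dataclass(frozen=True)
class Joint:
    """One tracked joint: name, position in mm (camera space), confidence 0-3."""

    name: JointName
    position: np.ndarray
    confidence: int = 3

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValidationError(f"joint position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValidationError(f"non-finite position for joint {self.name.value}")
        if not 0 <= int(self.confidence) <= 3:
            raise ValidationError(f"confidence must be in 0..3, got {self.confidence}")
        object.__setattr__(self, "position", pos)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Joint):
            return NotImplemented
        return (
            self.name == other.name
            and self.confidence == other.confidence
            and np.array_equal(self.position, other.position)
        )

    def __hash__(self) -> int:
        return hash((self.name, self.confidence, tuple(self.position)))


@dataclass(frozen=True)
class SkeletonFrame:
    """One time-stamped skeleton for one tracked body.

    A frame is *processable* by the contact detector only if it contains both
    ear joints and at least one thumb joint; it is *distance-checkable* only
    if it contains the pelvis joint.
    """

    timestamp: float
    body_id: int
    joints: Mapping[JointName, Joint]

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValidationError(f"timestamp must be >= 0, got {self.timestamp}")
        for name, joint in self.joints.items():
            if joint.name != name:
                raise ValidationError(
                    f"joint map key {name.value!r} does not match joint name {joint.name.value!r}"
                )

    def position(self, name: JointName) -> Optional[np.ndarray]:
        """Position of *name* in mm, or None if the joint is not tracked."""
        joint = self.joints.get(name)
        return None if joint is None else joint.position

    @property
    def is_processable(self) -> bool:
        return (
            JointName.EAR_LEFT in self.joints
            and JointName.EAR_RIGHT in self.joints
            and (JointName.THUMB_LEFT in self.joints or JointName.THUMB_RIGHT in self.joints)
        )

    @property
    def is_distance_checkable(self) -> bool:
        return JointName.PELVIS in self.joints


@dataclass(frozen=True)
class EventRecord:
    """A contact event: a maximal run of identically labeled contact frames.

    ``n_frames = 0`` is permitted only for truth annotations that record event
    intervals without per-frame counts.
    """

    event_id: int
    body_id: int
    start: float
    end: float
    label: str
    n_frames: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"event start {self.start} > end {self.end}")
        if self.label not in EVENT_LABELS:
            raise ValidationError(
                f"unknown event label {self.label!r}; permitted: {', '.join(EVENT_LABELS)}"
            )
        if self.n_frames < 0:
            raise ValidationError(f"n_frames must be >= 0, got {self.n_frames}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class FrameLabel:
    """Per-frame classifier output: contact state plus contact-area class.

    ``area`` is present iff ``state == "contact"``.  ``degraded`` marks frames
    where tracking loss (missing ears or thumbs) forced a no-contact label.
    """

    timestamp: float
    body_id: int
    state: str  # "contact" | "no_contact"
    area: Optional[str] = None
    hand: Optional[str] = None  # "left" | "right"
    degraded: bool = False

    def __post_init__(self) -> None:
        if self.state not in ("contact", "no_contact"):
            raise ValidationError(f"state must be contact|no_contact, got {self.state!r}")
        if (self.area is not None) != (self.state == "contact"):
            raise ValidationError("area must be present iff state == contact")
        if self.area is not None and self.area not in CONTACT_AREAS:
            raise ValidationError(f"unknown contact area {self.area!r}")
        if self.hand not in (None, "left", "right"):
            raise ValidationError(f"hand must be left|right, got {self.hand!r}")

    @property
    def key(self) -> tuple[str, Optional[str]]:
        """(state, area) pair used for run-length event grouping."""
        return (self.state, self.area)


# ---------------------------------------------------------------------------
# Formatting helpers (fixed precision for byte-stable output)

_MM = "{:.3f}"
_TS = "{:.6f}"


def _fmt_mm(x: float) -> str:
    s = _MM.format(x)
    return "0.000" if s == "-0.000" else s


def _fmt_ts(t: float) -> str:
    s = _TS.format(t)
    return "0.000000" if s == "-0.000000" else s


def _infer_format(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"format must be 'jsonl' or 'csv', got {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer stream format from suffix {suffix!r}; pass format=")


def _lookup_joint(raw: str, lineno: int) -> JointName:
    try:
        return _JOINT_BY_NAME[raw]
    except KeyError:
        raise ParseError(f"line {lineno}: unknown joint name {raw!r}") from None


# ---------------------------------------------------------------------------
# Skeleton streams


def read_skeleton_stream(
    path: Union[str, Path], format: Optional[str] = None
) -> list[SkeletonFrame]:
    """Read a skeleton stream (JSON-lines or long CSV) into SkeletonFrames.

    Frames are returned sorted by ``(timestamp, body_id)``.  Unknown joint
    names raise :class:`ParseError` naming the offending line; non-monotone
    timestamps within one body raise :class:`ValidationError`.
    """
    fmt = _infer_format(path, format)
    frames = _read_jsonl(path) if fmt == "jsonl" else _read_csv(path)
    frames.sort(key=lambda f: (f.timestamp, f.body_id))
    last_t: dict[int, float] = {}
    for f in frames:
        prev = last_t.get(f.body_id)
        if prev is not None and f.timestamp <= prev:
            raise ValidationError(
                f"non-monotone timestamps for body {f.body_id}: "
                f"{f.timestamp} follows {prev}"
            )
        last_t[f.body_id] = f.timestamp
    return frames


def _read_jsonl(path: Union[str, Path]) -> list[SkeletonFrame]:
    frames: list[SkeletonFrame] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"line {lineno}: invalid JSON ({exc.msg})") from None
            try:
                t = float(obj["t"])
                body = int(obj["body"])
                raw_joints = obj["joints"]
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"line {lineno}: malformed frame object ({exc})") from None
            joints: dict[JointName, Joint] = {}
            for raw_name, vals in raw_joints.items():
                name = _lookup_joint(raw_name, lineno)
                if not isinstance(vals, (list, tuple)) or len(vals) not in (3, 4):
                    raise ParseError(
                        f"line {lineno}: joint {raw_name!r} must be [x, y, z] or [x, y, z, conf]"
                    )
                conf = int(vals[3]) if len(vals) == 4 else 3
                joints[name] = Joint(name, np.array(vals[:3], dtype=float), conf)
            frames.append(SkeletonFrame(t, body, joints))
    return frames


_CSV_HEADER = ["timestamp_s", "body_id", "joint", "x_mm", "y_mm", "z_mm", "confidence"]


def _read_csv(path: Union[str, Path]) -> list[SkeletonFrame]:
    grouped: dict[tuple[float, int], dict[JointName, Joint]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _CSV_HEADER:
            raise ParseError(f"line 1: expected header {','.join(_CSV_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 7:
                raise ParseError(f"line {lineno}: expected 7 fields, got {len(row)}")
            try:
                t = float(row[0])
                body = int(row[1])
                xyz = np.array([float(row[3]), float(row[4]), float(row[5])])
                conf = int(row[6])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            name = _lookup_joint(row[2], lineno)
            joints = grouped.setdefault((t, body), {})
            joints[name] = Joint(name, xyz, conf)
    return [SkeletonFrame(t, body, joints) for (t, body), joints in grouped.items()]


def write_skeleton_stream(
    frames: Iterable[SkeletonFrame], path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write frames to *path*; output is byte-stable for fixed input.

    Frames are emitted sorted by ``(timestamp, body_id)`` with joints in the
    canonical 32-joint order, positions at 3 decimals (mm) and timestamps at
    6 decimals (s).
    """
    fmt = _infer_format(path, format)
    ordered = sorted(frames, key=lambda f: (f.timestamp, f.body_id))
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for f in ordered:
                parts = []
                for name in _JOINT_ORDER:
                    joint = f.joints.get(name)
                    if joint is None:
                        continue
                    x, y, z = joint.position
                    parts.append(
                        f'"{name.value}":[{_fmt_mm(x)},{_fmt_mm(y)},{_fmt_mm(z)},{joint.confidence}]'
                    )
                fh.write(
                    f'{{"t":{_fmt_ts(f.timestamp)},"body":{f.body_id},'
                    f'"joints":{{{",".join(parts)}}}}}\n'
                )
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(_CSV_HEADER)
            for f in ordered:
                for name in _JOINT_ORDER:
                    joint = f.joints.get(name)
                    if joint is None:
                        continue
                    x, y, z = joint.position
                    writer.writerow(
                        [
                            _fmt_ts(f.timestamp),
                            f.body_id,
                            name.value,
                            _fmt_mm(x),
                            _fmt_mm(y),
                            _fmt_mm(z),
                            joint.confidence,
                        ]
                    )


# ---------------------------------------------------------------------------
# Event records

_EVENTS_HEADER = ["event_id", "body_id", "start_s", "end_s", "label", "n_frames"]


def read_events(path: Union[str, Path]) -> list[EventRecord]:
    """Read an events CSV; returns records sorted by start time."""
    events: list[EventRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _EVENTS_HEADER:
            raise ParseError(f"line 1: expected header {','.join(_EVENTS_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 6:
                raise ParseError(f"line {lineno}: expected 6 fields, got {len(row)}")
            try:
                rec = EventRecord(
                    event_id=int(row[0]),
                    body_id=int(row[1]),
                    start=float(row[2]),
                    end=float(row[3]),
                    label=row[4],
                    n_frames=int(row[5]),
                )
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from None
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            events.append(rec)
    events.sort(key=lambda e: (e.start, e.body_id, e.event_id))
    return events


def write_events(events: Iterable[EventRecord], path: Union[str, Path]) -> None:
    """Write events sorted by start time; deterministic output."""
    ordered = sorted(events, key=lambda e: (e.start, e.body_id, e.event_id))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_EVENTS_HEADER)
        for e in ordered:
            writer.writerow(
                [e.event_id, e.body_id, _fmt_ts(e.start), _fmt_ts(e.end), e.label, e.n_frames]
            )


# ---------------------------------------------------------------------------
# Frame-label tables (output of the detection stage)

_LABELS_HEADER = ["timestamp_s", "body_id", "state", "area", "hand", "degraded"]


def write_frame_labels(labels: Iterable[FrameLabel], path: Union[str, Path]) -> None:
    ordered = sorted(labels, key=lambda l: (l.timestamp, l.body_id))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_LABELS_HEADER)
        for l in ordered:
            writer.writerow(
                [
                    _fmt_ts(l.timestamp),
                    l.body_id,
                    l.state,
                    l.area or "",
                    l.hand or "",
                    int(l.degraded),
                ]
            )


def read_frame_labels(path: Union[str, Path]) -> list[FrameLabel]:
    labels: list[FrameLabel] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _LABELS_HEADER:
            raise ParseError(f"line 1: expected header {','.join(_LABELS_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                labels.append(
                    FrameLabel(
                        timestamp=float(row[0]),
                        body_id=int(row[1]),
                        state=row[2],
                        area=row[3] or None,
                        hand=row[4] or None,
                        degraded=bool(int(row[5])),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    labels.sort(key=lambda l: (l.timestamp, l.body_id))
    return labels
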