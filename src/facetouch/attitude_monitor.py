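"""Event grouping, interpersonal-distance checks and behavioral reporting.

This stage turns the per-frame classifier output into *contact events*
(maximal runs of consecutive frames sharing the contact state and contact-area
label), raises real-time transition signals, checks the interpersonal distance
between tracked bodies against the 1 m rule, and at the end of an observation
assembles a statistical report on the observed person's hand-to-face attitude.

Events are defined purely as label runs: a single contact frame is an event,
and tracking jitter that splits a physical touch into several runs yields
several events (optional ``min_frames`` / ``merge_gap_s`` post-filters exist
but default to off).  An event's end time is the timestamp of its last contact
frame, so at a uniform frame rate a run of n frames has duration (n-1)/fps.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations, groupby
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .skeleton_io import (
    CONTACT_AREAS,
    EventRecord,
    FrameLabel,
    JointName,
    SkeletonFrame,
    _fmt_ts,
)

__all__ = [
    "Signal",
    "DistanceAlert",
    "AttitudeReport",
    "DEFAULT_DISTANCE_THRESHOLD_MM",
    "step",
    "group_events",
    "check_distance",
    "build_report",
    "write_report",
    "monitor_stream",
]

#: Interpersonal safety distance (the "at least 1 m" rule), in mm.
DEFAULT_DISTANCE_THRESHOLD_MM = 1000.0


@dataclass(frozen=True)
class Signal:
    """Real-time transition signal emitted when the frame label changes.

    kind is one of ``contact_started``, ``area_changed``, ``contact_ended``;
    area is set for the first two.
    """

    kind: str
    timestamp: float
    body_id: int
    area: Optional[str] = None


@dataclass(frozen=True)
class DistanceAlert:
    """An under-distance condition between two tracked bodies at one frame."""

    timestamp: float
    body_pair: tuple[int, int]
    distance: float  # mm
    threshold: float = DEFAULT_DISTANCE_THRESHOLD_MM

    def __post_init__(self) -> None:
        if self.distance >= self.threshold:
            raise ValueError("alert requires distance < threshold")


@dataclass
class AttitudeReport:
    """End-of-observation summary of contact behavior.

    Per-area counts sum to the total number of events; durations are in
    seconds and bounded by the observation span.
    """

    observation_span_s: float
    area_counts: dict[str, int]
    area_durations_s: dict[str, float]
    events_per_hour: float
    degraded_frames: int
    distance_alert_count: int
    events: list[EventRecord] = field(default_factory=list)

    @property
    def total_events(self) -> int:
        return sum(self.area_counts.values())

    @property
    def total_contact_duration_s(self) -> float:
        return sum(self.area_durations_s.values())


def step(previous: Optional[FrameLabel], current: FrameLabel) -> Optional[Signal]:
    """Compare the newly acquired frame label with the previous one.

    Emits ``contact_started`` on a no-contact to contact transition,
    ``area_changed`` when the contact-area label changes within a contact,
    ``contact_ended`` on contact to no-contact, and nothing otherwise.
    """
    if previous is not None:
        if previous.body_id != current.body_id:
            raise ValueError("step() compares labels of one body")
        if current.timestamp <= previous.timestamp:
            raise ValueError("labels must be in increasing time order")
    prev_contact = previous is not None and previous.state == "contact"
    cur_contact = current.state == "contact"
    if not prev_contact and cur_contact:
        return Signal("contact_started", current.timestamp, current.body_id, current.area)
    if prev_contact and cur_contact and previous.area != current.area:
        return Signal("area_changed", current.timestamp, current.body_id, current.area)
    if prev_contact and not cur_contact:
        return Signal("contact_ended", current.timestamp, current.body_id)
    return None


def group_events(
    labels: Sequence[FrameLabel],
    min_frames: int = 1,
    merge_gap_s: float = 0.0,
    first_event_id: int = 1,
) -> list[EventRecord]:
    """Run-length encode the (state, area) label sequence of one body.

    Maximal runs of contact frames sharing one area become one event with
    ``start``/``end`` the first/last frame timestamps and ``n_frames`` the run
    length.  ``min_frames`` drops shorter events and ``merge_gap_s`` merges
    same-area events separated by at most that gap; both default to off.
    """
    labels = sorted(labels, key=lambda l: l.timestamp)
    bodies = {l.body_id for l in labels}
    if len(bodies) > 1:
        raise ValueError(f"group_events expects labels of one body, got {sorted(bodies)}")
    events: list[EventRecord] = []
    for key, run_iter in groupby(labels, key=lambda l: l.key):
        state, area = key
        if state != "contact":
            continue
        run = list(run_iter)
        events.append(
            EventRecord(
                event_id=0,
                body_id=run[0].body_id,
                start=run[0].timestamp,
                end=run[-1].timestamp,
                label=area,  # type: ignore[arg-type]
                n_frames=len(run),
            )
        )
    if merge_gap_s > 0.0:
        merged: list[EventRecord] = []
        for ev in events:
            if (
                merged
                and merged[-1].label == ev.label
                and ev.start - merged[-1].end <= merge_gap_s
            ):
                prev = merged.pop()
                ev = EventRecord(
                    0, ev.body_id, prev.start, ev.end, ev.label, prev.n_frames + ev.n_frames
                )
            merged.append(ev)
        events = merged
    if min_frames > 1:
        events = [e for e in events if e.n_frames >= min_frames]
    return [
        EventRecord(first_event_id + i, e.body_id, e.start, e.end, e.label, e.n_frames)
        for i, e in enumerate(events)
    ]


def check_distance(
    frames: Sequence[SkeletonFrame],
    threshold_mm: float = DEFAULT_DISTANCE_THRESHOLD_MM,
) -> list[DistanceAlert]:
    """Pairwise pelvis-distance check between all bodies at one timestamp.

    Emits one alert per unordered body pair whose 3D Euclidean pelvis-pelvis
    distance falls below *threshold_mm*.  Bodies without a tracked pelvis are
    skipped (callers tally them).  Symmetric in the frame order.
    """
    checkable = sorted(
        (f for f in frames if f.is_distance_checkable), key=lambda f: f.body_id
    )
    alerts: list[DistanceAlert] = []
    for a, b in combinations(checkable, 2):
        dist = float(
            np.linalg.norm(a.position(JointName.PELVIS) - b.position(JointName.PELVIS))
        )
        if dist < threshold_mm:
            alerts.append(
                DistanceAlert(a.timestamp, (a.body_id, b.body_id), dist, threshold_mm)
            )
    return alerts


def build_report(
    labels: Sequence[FrameLabel],
    events: Sequence[EventRecord],
    alerts: Sequence[DistanceAlert] = (),
) -> AttitudeReport:
    """Assemble the end-of-observation attitude report from the label buffer."""
    counts = {area: 0 for area in CONTACT_AREAS}
    durations = {area: 0.0 for area in CONTACT_AREAS}
    for ev in events:
        counts[ev.label] += 1
        durations[ev.label] += ev.duration
    if labels:
        span = max(l.timestamp for l in labels) - min(l.timestamp for l in labels)
    else:
        span = 0.0
    n_events = sum(counts.values())
    per_hour = (n_events / span * 3600.0) if span > 0 else 0.0
    return AttitudeReport(
        observation_span_s=span,
        area_counts=counts,
        area_durations_s=durations,
        events_per_hour=per_hour,
        degraded_frames=sum(1 for l in labels if l.degraded),
        distance_alert_count=len(alerts),
        events=list(events),
    )


def write_report(report: AttitudeReport, path: Union[str, Path]) -> None:
    """Write the report CSV: summary header, per-area block, per-event table."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# observation_span_s={_fmt_ts(report.observation_span_s)}\n")
        fh.write(f"# total_events={report.total_events}\n")
        fh.write(f"# events_per_hour={report.events_per_hour:.3f}\n")
        fh.write(f"# degraded_frames={report.degraded_frames}\n")
        fh.write(f"# distance_alerts={report.distance_alert_count}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["area", "count", "total_duration_s"])
        for area in CONTACT_AREAS:
            writer.writerow(
                [area, report.area_counts[area], _fmt_ts(report.area_durations_s[area])]
            )
        writer.writerow(["event_id", "body_id", "start_s", "end_s", "label", "n_frames"])
        for e in sorted(report.events, key=lambda e: (e.start, e.body_id, e.event_id)):
            writer.writerow(
                [e.event_id, e.body_id, _fmt_ts(e.start), _fmt_ts(e.end), e.label, e.n_frames]
            )


def monitor_stream(
    frames: Sequence[SkeletonFrame],
    config=None,
    distance_threshold_mm: float = DEFAULT_DISTANCE_THRESHOLD_MM,
    min_frames: int = 1,
    merge_gap_s: float = 0.0,
) -> tuple[list[FrameLabel], list[EventRecord], list[DistanceAlert], AttitudeReport]:
    """Run detection + monitoring over a whole stream in one pass.

    Contact detection runs independently per body; the distance check runs
    across bodies at each shared timestamp.  Returns the frame labels, the
    contact events of all bodies (event ids unique across bodies), the
    distance alerts and the final report.
    """
    from .gesture_detection import DetectorConfig, label_frame

    cfg = config if config is not None else DetectorConfig()
    labels = [label_frame(f, cfg) for f in frames]

    per_body: dict[int, list[FrameLabel]] = {}
    for l in labels:
        per_body.setdefault(l.body_id, []).append(l)
    events: list[EventRecord] = []
    next_id = 1
    for body_id in sorted(per_body):
        body_events = group_events(
            per_body[body_id], min_frames=min_frames, merge_gap_s=merge_gap_s,
            first_event_id=next_id,
        )
        events.extend(body_events)
        next_id += len(body_events)

    alerts: list[DistanceAlert] = []
    by_time: dict[float, list[SkeletonFrame]] = {}
    for f in frames:
        by_time.setdefault(f.timestamp, []).append(f)
    for t in sorted(by_time):
        if len(by_time[t]) > 1:
            alerts.extend(check_distance(by_time[t], distance_threshold_mm))

    return labels, events, alerts, build_report(labels, events, alerts)
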