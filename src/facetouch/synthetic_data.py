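"""Synthetic skeleton-gesture simulator with known ground truth.

Emulates the validation scenario of a person standing ~2 m in front of a
depth sensor mounted at 170 cm, facing it, executing scripted hand-to-face
gestures: contacts with one of the six face areas, low-risk touches inside
the contact volume but away from every landmark, face-occlusion gestures
(hand raised between face and camera without touching), and idle periods.
Anthropometric presets cover the 5th/50th/95th percentile head breadth of an
adult male (14.8 / 15.7 / 16.8 cm).

The trunk and legs are posed statically from the anthropometric profile; only
the scripted hand chain (thumb, hand, handtip, wrist) moves.  A gesture's
thumb path is piecewise linear: from the rest pose (hands at hip height) to a
staging point on the ray from the head center through the gesture's anchor,
then radially inward to the anchor, so the thumb enters the contact volume
already inside the Voronoi cell of its target landmark and each scripted
gesture yields exactly one truth event.

Ground truth derives from the noiseless trajectory: truth frame labels are
the detector's output on the noise-free stream, truth contact events their
run-length grouping, and each occlusion gesture contributes one truth event
spanning its hold window (the detector, by design, emits nothing for it).
Jitter (isotropic Gaussian, default sd 5 mm — small against the >=100 mm
contact radius) and face/thumb joint dropout are then applied from a seeded
generator, so identical seeds give byte-identical streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .attitude_monitor import group_events
from .gesture_detection import (
    DetectorConfig,
    compute_head_sphere,
    label_frame,
)
from .skeleton_io import (
    CONTACT_AREAS,
    EventRecord,
    FrameLabel,
    Joint,
    JointName,
    SkeletonFrame,
    ValidationError,
)

__all__ = [
    "AnthropometricProfile",
    "P05",
    "P50",
    "P95",
    "PROFILES",
    "GestureSpec",
    "GestureScript",
    "NoiseModel",
    "generate_stream",
    "generate_validation_set",
    "generate_multibody",
]

#: Default sensor geometry of the emulated setup.
DEFAULT_FPS = 30.0
DEFAULT_STANDING_DISTANCE_MM = 2000.0
DEFAULT_SENSOR_HEIGHT_MM = 1700.0

#: Joints subject to tracking dropout (the ones the detector depends on).
_DROPOUT_JOINTS = (
    JointName.EAR_LEFT,
    JointName.EAR_RIGHT,
    JointName.EYE_LEFT,
    JointName.EYE_RIGHT,
    JointName.NOSE,
    JointName.THUMB_LEFT,
    JointName.THUMB_RIGHT,
)

_GESTURE_KINDS = ("contact", "low_risk_touch", "occlusion", "idle")

#: Contact-gesture targets -> face joint anchoring the approach.
_TARGET_JOINT = {
    "mouth_nose": JointName.NOSE,
    "right_eye": JointName.EYE_RIGHT,
    "left_eye": JointName.EYE_LEFT,
    "right_ear": JointName.EAR_RIGHT,
    "left_ear": JointName.EAR_LEFT,
}


@dataclass(frozen=True)
class AnthropometricProfile:
    """Body dimensions (cm) posing the synthetic skeleton.

    ``head_breadth`` is the inter-ear distance driving every detector
    threshold; the named presets carry the 5th/50th/95th percentile values.
    """

    name: str
    head_breadth: float  # cm, inter-ear distance
    height: float  # cm, standing stature
    shoulder_width: float  # cm, biacromial breadth
    arm_length: float  # cm, shoulder to wrist

    def __post_init__(self) -> None:
        if min(self.head_breadth, self.height, self.shoulder_width, self.arm_length) <= 0:
            raise ValidationError("anthropometric dimensions must be positive")


P05 = AnthropometricProfile("p05", head_breadth=14.8, height=164.5, shoulder_width=36.7, arm_length=70.0)
P50 = AnthropometricProfile("p50", head_breadth=15.7, height=175.6, shoulder_width=39.7, arm_length=75.0)
P95 = AnthropometricProfile("p95", head_breadth=16.8, height=186.6, shoulder_width=42.7, arm_length=80.0)
PROFILES: Mapping[str, AnthropometricProfile] = {"p05": P05, "p50": P50, "p95": P95}


@dataclass(frozen=True)
class GestureSpec:
    """One scripted gesture.

    kind
        ``contact`` (touch the face area in ``target``), ``low_risk_touch``
        (enter the contact volume away from every landmark), ``occlusion``
        (raise the hand between face and camera without touching) or ``idle``.
    onset / approach / hold
        Start time, one-way approach duration and on-target hold duration in
        seconds; the full gesture occupies ``[onset, onset + 2*approach + hold]``.
    """

    kind: str
    onset: float
    target: Optional[str] = None
    approach: float = 0.2
    hold: float = 0.3
    hand: str = "right"

    def __post_init__(self) -> None:
        if self.kind not in _GESTURE_KINDS:
            raise ValidationError(f"unknown gesture kind {self.kind!r}")
        if self.kind == "contact":
            if self.target not in _TARGET_JOINT:
                raise ValidationError(
                    f"contact gesture target must be one of {sorted(_TARGET_JOINT)}, "
                    f"got {self.target!r}"
                )
        elif self.target is not None:
            raise ValidationError(f"{self.kind} gestures take no target")
        if self.onset < 0 or self.approach <= 0 or self.hold < 0:
            raise ValidationError("gesture timing must be non-negative (approach > 0)")
        if self.hand not in ("left", "right"):
            raise ValidationError(f"hand must be left|right, got {self.hand!r}")

    @property
    def end(self) -> float:
        return self.onset + 2.0 * self.approach + self.hold

    @property
    def hold_start(self) -> float:
        return self.onset + self.approach

    @property
    def hold_end(self) -> float:
        return self.onset + self.approach + self.hold


@dataclass(frozen=True)
class GestureScript:
    """Ordered gesture sequence; gestures must not overlap per hand."""

    gestures: tuple[GestureSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gestures", tuple(self.gestures))
        by_hand: dict[str, list[GestureSpec]] = {"left": [], "right": []}
        for g in self.gestures:
            if g.kind != "idle":
                by_hand[g.hand].append(g)
        for hand, specs in by_hand.items():
            specs.sort(key=lambda g: g.onset)
            for prev, cur in zip(specs, specs[1:]):
                if cur.onset < prev.end:
                    raise ValidationError(
                        f"overlapping {hand}-hand gestures at t={cur.onset:.3f}s "
                        f"(previous one ends at t={prev.end:.3f}s)"
                    )

    @property
    def duration(self) -> float:
        ends = [g.end for g in self.gestures if g.kind != "idle"]
        idle_ends = [g.onset + g.hold for g in self.gestures if g.kind == "idle"]
        return max(ends + idle_ends, default=0.0)


@dataclass(frozen=True)
class NoiseModel:
    """Tracking-noise model: per-joint Gaussian jitter and joint dropout.

    Defaults: 5 mm isotropic jitter (small relative to the >=100 mm contact
    radius), no dropout.  Identical seeds yield identical streams.
    """

    jitter_sd_mm: float = 5.0
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd_mm < 0:
            raise ValidationError("jitter_sd_mm must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValidationError("dropout_prob must be in [0, 1]")


NOISELESS = NoiseModel(jitter_sd_mm=0.0, dropout_prob=0.0, seed=0)


# ---------------------------------------------------------------------------
# Rest pose


def _rest_pose(
    profile: AnthropometricProfile,
    distance_mm: float,
    sensor_height_mm: float,
) -> dict[JointName, np.ndarray]:
    """Static 32-joint standing pose facing the sensor.

    Camera space: x right (so the subject's left side has positive x), y down,
    z away from the sensor; the sensor sits ``sensor_height_mm`` above the
    floor and the subject stands at ``distance_mm``.
    """
    d = 10.0 * profile.head_breadth  # inter-ear distance, mm
    r = 0.5 * d
    h = 10.0 * profile.height
    sw = 10.0 * profile.shoulder_width
    arm = 10.0 * profile.arm_length
    z0 = distance_mm

    def at_height(mm_above_floor: float) -> float:
        return sensor_height_mm - mm_above_floor  # y grows downward

    center = np.array([0.0, at_height(h - 110.0), z0])  # head center (between ears)
    y_sh = at_height(0.82 * h)
    y_pel = at_height(0.53 * h)

    J: dict[JointName, np.ndarray] = {}
    J[JointName.HEAD] = center.copy()
    J[JointName.EAR_LEFT] = center + np.array([r, 0.0, 0.0])
    J[JointName.EAR_RIGHT] = center + np.array([-r, 0.0, 0.0])
    J[JointName.EYE_LEFT] = center + r * np.array([0.35, -0.25, -0.85])
    J[JointName.EYE_RIGHT] = center + r * np.array([-0.35, -0.25, -0.85])
    J[JointName.NOSE] = center + r * np.array([0.0, 0.10, -1.0])
    J[JointName.NECK] = center + np.array([0.0, 0.9 * d, 0.1 * d])

    J[JointName.PELVIS] = np.array([0.0, y_pel, z0])
    J[JointName.SPINE_NAVEL] = np.array([0.0, y_pel - 0.09 * h, z0])
    J[JointName.SPINE_CHEST] = np.array([0.0, y_pel - 0.20 * h, z0])
    J[JointName.CLAVICLE_LEFT] = np.array([0.25 * sw, y_sh - 10.0, z0])
    J[JointName.CLAVICLE_RIGHT] = np.array([-0.25 * sw, y_sh - 10.0, z0])
    J[JointName.SHOULDER_LEFT] = np.array([0.5 * sw, y_sh, z0])
    J[JointName.SHOULDER_RIGHT] = np.array([-0.5 * sw, y_sh, z0])

    for side, sx in (("LEFT", 1.0), ("RIGHT", -1.0)):
        shoulder = J[JointName[f"SHOULDER_{side}"]]
        elbow = shoulder + np.array([sx * 30.0, 0.45 * arm, -20.0])
        wrist = elbow + np.array([sx * 10.0, 0.40 * arm, -30.0])
        J[JointName[f"ELBOW_{side}"]] = elbow
        J[JointName[f"WRIST_{side}"]] = wrist
        J[JointName[f"HAND_{side}"]] = wrist + np.array([0.0, 60.0, -20.0])
        J[JointName[f"HANDTIP_{side}"]] = wrist + np.array([0.0, 130.0, -30.0])
        J[JointName[f"THUMB_{side}"]] = wrist + np.array([-sx * 30.0, 40.0, -40.0])

        hip = J[JointName.PELVIS] + np.array([sx * 90.0, 20.0, 0.0])
        knee = hip + np.array([0.0, 0.245 * h, 10.0])
        ankle = knee + np.array([0.0, 0.245 * h, 10.0])
        J[JointName[f"HIP_{side}"]] = hip
        J[JointName[f"KNEE_{side}"]] = knee
        J[JointName[f"ANKLE_{side}"]] = ankle
        J[JointName[f"FOOT_{side}"]] = ankle + np.array([0.0, 30.0, -150.0])

    return J


def _frame_from_positions(
    t: float, body_id: int, positions: Mapping[JointName, np.ndarray]
) -> SkeletonFrame:
    return SkeletonFrame(
        timestamp=t,
        body_id=body_id,
        joints={name: Joint(name, pos.copy()) for name, pos in positions.items()},
    )


# ---------------------------------------------------------------------------
# Gesture anchors and thumb trajectory


def _gesture_anchor(
    spec: GestureSpec,
    rest: Mapping[JointName, np.ndarray],
    config: DetectorConfig,
    contact_offset_mm: float,
) -> np.ndarray:
    """End point of the thumb path for a gesture, from the rest geometry."""
    frame = _frame_from_positions(0.0, 0, rest)
    sphere = compute_head_sphere(frame, config.contact_ratio, config.lowrisk_ratio)
    center = sphere.center
    if spec.kind == "contact":
        lm = rest[_TARGET_JOINT[spec.target]]
        u = (center - lm) / np.linalg.norm(center - lm)
        return lm + contact_offset_mm * u  # just inside, nearest to the target
    if spec.kind == "low_risk_touch":
        # behind the head: inside the contact volume, far from every landmark
        return center + np.array([0.0, 0.0, 0.95 * sphere.contact_radius])
    if spec.kind == "occlusion":
        # on the sensor-to-head-center ray, outside the contact volume
        u = center / np.linalg.norm(center)
        return center - 1.5 * sphere.contact_radius * u
    raise ValidationError(f"gesture kind {spec.kind!r} has no anchor")


#: Radial distance (mm beyond the contact radius) of the staging point where
#: the approach path joins the target ray before sliding inward.
_STAGING_MARGIN_MM = 180.0

#: Fraction of the approach time spent reaching the staging point.
_STAGING_FRACTION = 0.7


def _thumb_position(
    spec: GestureSpec,
    t: float,
    rest_thumb: np.ndarray,
    anchor: np.ndarray,
    center: np.ndarray,
    contact_radius: float,
) -> np.ndarray:
    """Thumb position at time *t* within one gesture (piecewise linear)."""
    w = anchor - center
    w = w / np.linalg.norm(w)
    staging = center + (contact_radius + _STAGING_MARGIN_MM) * w

    def approach_point(s: float) -> np.ndarray:
        # s in [0, 1]: rest -> staging -> anchor
        if s <= _STAGING_FRACTION:
            a = s / _STAGING_FRACTION
            return rest_thumb + a * (staging - rest_thumb)
        a = (s - _STAGING_FRACTION) / (1.0 - _STAGING_FRACTION)
        return staging + a * (anchor - staging)

    if t < spec.onset or t > spec.end:
        return rest_thumb
    if t < spec.hold_start:
        return approach_point((t - spec.onset) / spec.approach)
    if t <= spec.hold_end:
        return anchor
    return approach_point((spec.end - t) / spec.approach)


# ---------------------------------------------------------------------------
# Stream generation


def generate_stream(
    script: GestureScript,
    profile: AnthropometricProfile = P50,
    noise: NoiseModel = NoiseModel(),
    fps: float = DEFAULT_FPS,
    standing_distance_mm: float = DEFAULT_STANDING_DISTANCE_MM,
    sensor_height_mm: float = DEFAULT_SENSOR_HEIGHT_MM,
    contact_offset_mm: float = 10.0,
    body_id: int = 0,
    config: DetectorConfig = DetectorConfig(),
    tail_s: float = 0.5,
) -> tuple[list[SkeletonFrame], list[EventRecord], list[FrameLabel]]:
    """Simulate a skeleton stream executing *script*; return stream + truth.

    Returns ``(frames, truth_events, truth_labels)``.  Truth is computed on
    the noiseless trajectory: contact/low-risk gestures via the frame
    classifier itself (so truth events carry exactly the scripted areas),
    occlusion gestures as one truth event per gesture spanning its hold
    window.  Noise (jitter, dropout) is applied only to the returned frames.
    """
    if fps <= 0:
        raise ValidationError("fps must be positive")
    rest = _rest_pose(profile, standing_distance_mm, sensor_height_mm)
    sphere = compute_head_sphere(
        _frame_from_positions(0.0, body_id, rest), config.contact_ratio, config.lowrisk_ratio
    )
    moving = [g for g in script.gestures if g.kind != "idle"]
    anchors = {id(g): _gesture_anchor(g, rest, config, contact_offset_mm) for g in moving}

    n_frames = int(round((script.duration + tail_s) * fps)) + 1
    times = [i / fps for i in range(n_frames)]

    clean_frames: list[SkeletonFrame] = []
    for t in times:
        pos = {name: p.copy() for name, p in rest.items()}
        for g in moving:
            if g.onset <= t <= g.end:
                side = g.hand.upper()
                thumb_name = JointName[f"THUMB_{side}"]
                thumb = _thumb_position(
                    g, t, rest[thumb_name], anchors[id(g)], sphere.center, sphere.contact_radius
                )
                delta = thumb - rest[thumb_name]
                pos[thumb_name] = thumb
                for chain in ("WRIST", "HAND", "HANDTIP"):
                    name = JointName[f"{chain}_{side}"]
                    pos[name] = rest[name] + delta
        clean_frames.append(_frame_from_positions(t, body_id, pos))

    truth_labels = [label_frame(f, config) for f in clean_frames]
    truth_events = group_events(truth_labels)
    for g in moving:
        if g.kind != "occlusion":
            continue
        window = [t for t in times if g.hold_start - 1e-9 <= t <= g.hold_end + 1e-9]
        if not window:
            continue
        truth_events.append(
            EventRecord(0, body_id, window[0], window[-1], "occlusion", len(window))
        )
    truth_events.sort(key=lambda e: e.start)
    truth_events = [
        EventRecord(i + 1, e.body_id, e.start, e.end, e.label, e.n_frames)
        for i, e in enumerate(truth_events)
    ]

    frames = _apply_noise(clean_frames, noise)
    return frames, truth_events, truth_labels


def _apply_noise(frames: Sequence[SkeletonFrame], noise: NoiseModel) -> list[SkeletonFrame]:
    if noise.jitter_sd_mm == 0.0 and noise.dropout_prob == 0.0:
        return list(frames)
    rng = np.random.default_rng(noise.seed)
    noisy: list[SkeletonFrame] = []
    for f in frames:
        joints: dict[JointName, Joint] = {}
        for name in JointName:  # canonical order keeps the rng stream stable
            joint = f.joints.get(name)
            if joint is None:
                continue
            if name in _DROPOUT_JOINTS and noise.dropout_prob > 0.0:
                if rng.random() < noise.dropout_prob:
                    continue
            pos = joint.position
            if noise.jitter_sd_mm > 0.0:
                pos = pos + rng.normal(0.0, noise.jitter_sd_mm, size=3)
            joints[name] = Joint(name, pos, joint.confidence)
        noisy.append(SkeletonFrame(f.timestamp, f.body_id, joints))
    return noisy


# ---------------------------------------------------------------------------
# Validation-set and multi-body generation


def generate_validation_set(
    n_events: Mapping[str, int],
    profile: AnthropometricProfile = P50,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    fps: float = DEFAULT_FPS,
    gap_s: float = 0.3,
    **stream_kwargs,
) -> tuple[list[SkeletonFrame], list[EventRecord], GestureScript]:
    """Simulate a stream whose truth contains a requested per-class event mix.

    *n_events* maps each of the seven truth classes (six contact areas plus
    ``occlusion``) to a count.  Gesture order and executing hand are
    randomized from *seed*; gestures are separated by idle gaps.
    Returns ``(frames, truth_events, script)``.
    """
    allowed = set(CONTACT_AREAS) | {"occlusion"}
    unknown = set(n_events) - allowed
    if unknown:
        raise ValidationError(f"unknown truth classes {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    pool: list[str] = []
    for cls in sorted(n_events):
        if n_events[cls] < 0:
            raise ValidationError("event counts must be >= 0")
        pool.extend([cls] * n_events[cls])
    rng.shuffle(pool)

    gestures: list[GestureSpec] = []
    t = 0.5
    for cls in pool:
        hand = "left" if rng.random() < 0.5 else "right"
        if cls == "occlusion":
            spec = GestureSpec("occlusion", onset=t, hand=hand)
        elif cls == "low_risk":
            spec = GestureSpec("low_risk_touch", onset=t, hand=hand)
        else:
            spec = GestureSpec("contact", onset=t, target=cls, hand=hand)
        gestures.append(spec)
        t = spec.end + gap_s
    script = GestureScript(tuple(gestures))
    frames, truth_events, _labels = generate_stream(
        script, profile=profile, noise=noise, fps=fps, **stream_kwargs
    )
    return frames, truth_events, script


def generate_multibody(
    streams: Sequence[Sequence[SkeletonFrame]], separation_mm: float
) -> list[SkeletonFrame]:
    """Merge single-body streams into one multi-body stream.

    Bodies are translated in the floor (x, z) plane to the vertices of a
    regular polygon with side length *separation_mm* (for two or three bodies
    all pairwise pelvis distances equal the separation) and given distinct
    ids.  Frames are returned sorted by (timestamp, body_id).
    """
    n = len(streams)
    if n < 2:
        raise ValidationError("generate_multibody needs at least two streams")
    if separation_mm <= 0:
        raise ValidationError("separation must be positive")
    circumradius = separation_mm / (2.0 * math.sin(math.pi / n))
    merged: list[SkeletonFrame] = []
    for k, stream in enumerate(streams):
        angle = 2.0 * math.pi * k / n
        offset = np.array(
            [circumradius * math.cos(angle), 0.0, circumradius * math.sin(angle)]
        )
        for f in stream:
            joints = {
                name: Joint(name, j.position + offset, j.confidence)
                for name, j in f.joints.items()
            }
            merged.append(SkeletonFrame(f.timestamp, k, joints))
    merged.sort(key=lambda f: (f.timestamp, f.body_id))
    return merged
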