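"""Hand-to-face contact detection and contact-area classification.

The head is modeled per frame as a sphere centered at the midpoint of the two
ear joints, with diameter equal to the inter-ear distance.  A concentric
*contact volume* with radius 70% of the inter-ear distance defines contact:
any frame in which a thumb joint lies inside that volume is a contact frame.

Contact frames are then classified by the face landmark nearest to the thumb
(nose, mouth, ears, eyes), partitioning the head sphere Voronoi-style.  If the
thumb is farther than a secondary threshold (75% of the inter-ear distance)
from every landmark, the contact is assigned to the *low-risk* area away from
the mucous membranes.  Since the mouth region borders the nose region, the two
are merged into a single mouth-nose class, yielding six contact classes.

Both ratios scale with the tracked inter-ear distance and therefore adapt to
the subject's anthropometrics: across the 5th-95th percentile head breadth of
an adult male (14.8-16.8 cm) the contact radius spans 10.36-11.76 cm.

All thresholds are inclusive (a distance exactly at a threshold counts as
inside / at-risk), favoring sensitivity to risk contacts.  Classification is a
pure function of a single frame; no cross-frame state is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .skeleton_io import FrameLabel, JointName, SkeletonFrame

__all__ = [
    "DetectorConfig",
    "HeadSphere",
    "FaceLandmarks",
    "DegenerateGeometryError",
    "MissingJointError",
    "LANDMARK_PRIORITY",
    "compute_head_sphere",
    "derive_mouth_point",
    "face_landmarks",
    "detect_contact",
    "classify_contact_area",
    "merge_areas",
    "label_frame",
]

#: Fixed tie-break priority for equidistant landmarks (first wins).
LANDMARK_PRIORITY: tuple[str, ...] = (
    "nose",
    "mouth",
    "right_eye",
    "left_eye",
    "right_ear",
    "left_ear",
)

#: 7-way (pre-merge) label -> 6-way contact-area class.
_MERGE = {
    "nose": "mouth_nose",
    "mouth": "mouth_nose",
    "right_eye": "right_eye",
    "left_eye": "left_eye",
    "right_ear": "right_ear",
    "left_ear": "left_ear",
    "low_risk": "low_risk",
}

#: Fraction of the inter-ear distance offsetting the synthetic mouth landmark
#: from the nose along the head-to-neck axis.
MOUTH_OFFSET_RATIO = 0.25


class DegenerateGeometryError(ValueError):
    """Head geometry cannot be built (e.g. coincident ear joints)."""


class MissingJointError(KeyError):
    """A joint required by an operation is not tracked in the frame."""


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable detector parameters.

    contact_ratio
        Contact-volume radius as a fraction of the inter-ear distance
        (default 0.70).
    lowrisk_ratio
        Secondary low-risk threshold as a fraction of the inter-ear distance
        (default 0.75).  Must exceed nothing in particular, but with the
        defaults the low-risk threshold lies just outside the contact radius.
    """

    contact_ratio: float = 0.70
    lowrisk_ratio: float = 0.75

    def __post_init__(self) -> None:
        if self.contact_ratio <= 0 or self.lowrisk_ratio <= 0:
            raise ValueError("detector ratios must be positive")


@dataclass(frozen=True)
class HeadSphere:
    """Per-frame head model: center, head radius and the two thresholds.

    Invariants (with d = inter-ear distance = 2 * head_radius):
    ``contact_radius = contact_ratio * d`` and
    ``lowrisk_threshold = lowrisk_ratio * d``.
    """

    center: np.ndarray  # mm
    head_radius: float  # mm, half the inter-ear distance
    contact_radius: float  # mm
    lowrisk_threshold: float  # mm
    contact_ratio: float = 0.70
    lowrisk_ratio: float = 0.75

    @property
    def inter_ear_distance(self) -> float:
        return 2.0 * self.head_radius


@dataclass(frozen=True)
class FaceLandmarks:
    """Positions (mm) of the six classification targets; None if untracked.

    The mouth is synthesized from the nose (the 32-joint skeleton has no mouth
    joint): nose offset by 0.25 x inter-ear distance along the head-to-neck
    direction, so it sits below the nose for any head pose.
    """

    nose: Optional[np.ndarray] = None
    mouth: Optional[np.ndarray] = None
    right_ear: Optional[np.ndarray] = None
    left_ear: Optional[np.ndarray] = None
    right_eye: Optional[np.ndarray] = None
    left_eye: Optional[np.ndarray] = None

    def available(self) -> list[tuple[str, np.ndarray]]:
        """(label, position) pairs for tracked landmarks, in priority order."""
        out = []
        for label in LANDMARK_PRIORITY:
            pos = getattr(self, label)
            if pos is not None:
                out.append((label, pos))
        return out


def compute_head_sphere(
    frame: SkeletonFrame,
    contact_ratio: float = 0.70,
    lowrisk_ratio: float = 0.75,
) -> HeadSphere:
    """Build the head sphere and contact volume from the ear joints.

    Raises :class:`MissingJointError` if either ear is untracked (callers
    treat this as a degraded frame) and :class:`DegenerateGeometryError` if
    the ears coincide.
    """
    left = frame.position(JointName.EAR_LEFT)
    right = frame.position(JointName.EAR_RIGHT)
    if left is None or right is None:
        raise MissingJointError("both ear joints are required to model the head")
    d = float(np.linalg.norm(left - right))
    if d <= 0.0:
        raise DegenerateGeometryError("inter-ear distance is zero")
    return HeadSphere(
        center=0.5 * (left + right),
        head_radius=0.5 * d,
        contact_radius=contact_ratio * d,
        lowrisk_threshold=lowrisk_ratio * d,
        contact_ratio=contact_ratio,
        lowrisk_ratio=lowrisk_ratio,
    )


def derive_mouth_point(frame: SkeletonFrame) -> np.ndarray:
    """Synthesize a mouth landmark below the nose.

    mouth = nose + 0.25 x inter-ear-distance x unit(neck - head).  If the neck
    or head joint is missing the nose position is returned unchanged (mouth
    and nose are merged downstream, so the fallback is inconsequential).
    """
    nose = frame.position(JointName.NOSE)
    if nose is None:
        raise MissingJointError("nose joint required to derive the mouth point")
    head = frame.position(JointName.HEAD)
    neck = frame.position(JointName.NECK)
    left = frame.position(JointName.EAR_LEFT)
    right = frame.position(JointName.EAR_RIGHT)
    if head is None or neck is None or left is None or right is None:
        return nose.copy()
    axis = neck - head
    norm = float(np.linalg.norm(axis))
    if norm == 0.0:
        return nose.copy()
    inter_ear = float(np.linalg.norm(left - right))
    return nose + MOUTH_OFFSET_RATIO * inter_ear * (axis / norm)


def face_landmarks(frame: SkeletonFrame) -> FaceLandmarks:
    """Collect the six classification landmarks tracked in *frame*."""
    nose = frame.position(JointName.NOSE)
    mouth = None if nose is None else derive_mouth_point(frame)
    return FaceLandmarks(
        nose=nose,
        mouth=mouth,
        right_ear=frame.position(JointName.EAR_RIGHT),
        left_ear=frame.position(JointName.EAR_LEFT),
        right_eye=frame.position(JointName.EYE_RIGHT),
        left_eye=frame.position(JointName.EYE_LEFT),
    )


def detect_contact(
    frame: SkeletonFrame, sphere: HeadSphere
) -> tuple[bool, Optional[str], Optional[np.ndarray]]:
    """Test whether a thumb joint lies inside the contact volume.

    Returns ``(in_contact, hand, thumb_position)``.  With both thumbs tracked
    the one nearer the sphere center decides; the boundary is inclusive.
    Raises :class:`MissingJointError` when no thumb is tracked.
    """
    candidates: list[tuple[float, str, np.ndarray]] = []
    for hand, name in (("left", JointName.THUMB_LEFT), ("right", JointName.THUMB_RIGHT)):
        pos = frame.position(name)
        if pos is not None:
            candidates.append((float(np.linalg.norm(pos - sphere.center)), hand, pos))
    if not candidates:
        raise MissingJointError("no thumb joint tracked")
    dist, hand, pos = min(candidates, key=lambda c: c[0])
    if dist <= sphere.contact_radius:
        return True, hand, pos
    return False, None, None


def classify_contact_area(
    thumb_position: np.ndarray, landmarks: FaceLandmarks, sphere: HeadSphere
) -> str:
    """Nearest-landmark (Voronoi-style) 7-way classification of a contact.

    Returns the pre-merge label: one of the six landmark labels or
    ``low_risk`` when the thumb is farther than the secondary threshold from
    every available landmark.  Ties are broken by the fixed priority order
    nose > mouth > right_eye > left_eye > right_ear > left_ear.  With no
    landmarks tracked at all the contact defaults to ``low_risk``.
    """
    best_label: Optional[str] = None
    best_dist = np.inf
    for label, pos in landmarks.available():
        dist = float(np.linalg.norm(thumb_position - pos))
        if dist < best_dist:  # strict: earlier (higher-priority) label keeps ties
            best_dist = dist
            best_label = label
    if best_label is None or best_dist > sphere.lowrisk_threshold:
        return "low_risk"
    return best_label


def merge_areas(area_7way: str) -> str:
    """Collapse the 7-way pre-merge label to the six contact classes."""
    try:
        return _MERGE[area_7way]
    except KeyError:
        raise ValueError(f"unknown 7-way area label {area_7way!r}") from None


def label_frame(frame: SkeletonFrame, config: DetectorConfig = DetectorConfig()) -> FrameLabel:
    """Classify one frame: head sphere -> contact test -> area -> merge.

    Frames that are not processable (missing both thumbs or either ear) are
    labeled no-contact with ``degraded=True``; face-occlusion gestures produce
    plain no-contact frames since no thumb enters the contact volume.
    """
    if not frame.is_processable:
        return FrameLabel(frame.timestamp, frame.body_id, "no_contact", degraded=True)
    sphere = compute_head_sphere(frame, config.contact_ratio, config.lowrisk_ratio)
    in_contact, hand, thumb = detect_contact(frame, sphere)
    if not in_contact:
        return FrameLabel(frame.timestamp, frame.body_id, "no_contact")
    area = merge_areas(classify_contact_area(thumb, face_landmarks(frame), sphere))
    return FrameLabel(frame.timestamp, frame.body_id, "contact", area=area, hand=hand)
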