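"""Shared fixtures: frame builders, printed-table fixture, brute-force oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from facetouch.skeleton_io import Joint, JointName, SkeletonFrame

# The published seven-class confusion matrix of the validation experiment
# (rows = classifier classes, columns = truth classes, order: mouth_nose,
# right_eye, left_eye, right_ear, left_ear, low_risk, occlusion).
TABLE1 = np.array(
    [
        [74, 7, 14, 0, 0, 1, 0],
        [12, 55, 1, 9, 0, 1, 0],
        [7, 0, 64, 0, 5, 1, 0],
        [0, 1, 0, 69, 0, 6, 0],
        [0, 1, 1, 0, 68, 6, 0],
        [0, 5, 2, 4, 7, 64, 5],
        [0, 0, 0, 0, 0, 20, 65],
    ],
    dtype=int,
)

# Its published three-class clustering (risk / no-risk / occlusion).
TABLE2 = np.array(
    [
        [234, 17, 0],
        [10, 224, 5],
        [0, 20, 65],
    ],
    dtype=int,
)


def make_frame(joints: dict[JointName, tuple | list | np.ndarray],
               t: float = 0.0, body: int = 0) -> SkeletonFrame:
    """Build a SkeletonFrame from a {joint: position} mapping."""
    return SkeletonFrame(
        timestamp=t,
        body_id=body,
        joints={n: Joint(n, np.asarray(p, dtype=float)) for n, p in joints.items()},
    )


def head_joints(
    center=(0.0, 0.0, 2000.0), inter_ear: float = 150.0
) -> dict[JointName, np.ndarray]:
    """A plausible head-joint layout: ears on x, eyes/nose toward -z."""
    c = np.asarray(center, dtype=float)
    r = inter_ear / 2.0
    return {
        JointName.EAR_LEFT: c + [r, 0.0, 0.0],
        JointName.EAR_RIGHT: c + [-r, 0.0, 0.0],
        JointName.EYE_LEFT: c + np.array([0.35, -0.25, -0.85]) * r,
        JointName.EYE_RIGHT: c + np.array([-0.35, -0.25, -0.85]) * r,
        JointName.NOSE: c + np.array([0.0, 0.10, -1.0]) * r,
        JointName.HEAD: c.copy(),
        JointName.NECK: c + [0.0, 1.8 * r, 0.3 * r],
    }


# ---------------------------------------------------------------------------
# Independent straight-line oracle for the frame classifier: explicit
# distances and thresholds in plain Python, no shared code with the package.

_ORACLE_PRIORITY = ("nose", "mouth", "right_eye", "left_eye", "right_ear", "left_ear")
_ORACLE_MERGE = {"nose": "mouth_nose", "mouth": "mouth_nose"}


def _dist(a, b) -> float:
    return math.sqrt(sum((float(x) - float(y)) ** 2 for x, y in zip(a, b)))


def oracle_label_frame(frame: SkeletonFrame, contact_ratio=0.70, lowrisk_ratio=0.75):
    """Reference classifier: returns (state, area_or_None, hand_or_None, degraded)."""
    pos = {n.value: tuple(j.position) for n, j in frame.joints.items()}
    ears = ("ear_left" in pos) and ("ear_right" in pos)
    thumbs = [h for h in ("left", "right") if f"thumb_{h}" in pos]
    if not ears or not thumbs:
        return ("no_contact", None, None, True)

    el, er = pos["ear_left"], pos["ear_right"]
    d = _dist(el, er)
    center = tuple((a + b) / 2.0 for a, b in zip(el, er))
    contact_radius = contact_ratio * d
    lowrisk_threshold = lowrisk_ratio * d

    best_hand, best_thumb, best = None, None, float("inf")
    for hand in thumbs:
        p = pos[f"thumb_{hand}"]
        dist = _dist(p, center)
        if dist < best:
            best, best_hand, best_thumb = dist, hand, p
    if best > contact_radius:
        return ("no_contact", None, None, False)

    landmarks = {}
    if "nose" in pos:
        landmarks["nose"] = pos["nose"]
        if "head" in pos and "neck" in pos:
            axis = tuple(n - h for n, h in zip(pos["neck"], pos["head"]))
            norm = math.sqrt(sum(a * a for a in axis))
            if norm > 0:
                landmarks["mouth"] = tuple(
                    n + 0.25 * d * a / norm for n, a in zip(pos["nose"], axis)
                )
            else:
                landmarks["mouth"] = pos["nose"]
        else:
            landmarks["mouth"] = pos["nose"]
    for key, joint in (
        ("right_ear", "ear_right"),
        ("left_ear", "ear_left"),
        ("right_eye", "eye_right"),
        ("left_eye", "eye_left"),
    ):
        if joint in pos:
            landmarks[key] = pos[joint]

    area, min_d = None, float("inf")
    for label in _ORACLE_PRIORITY:
        if label in landmarks:
            dist = _dist(best_thumb, landmarks[label])
            if dist < min_d:
                min_d, area = dist, label
    if area is None or min_d > lowrisk_threshold:
        merged = "low_risk"
    else:
        merged = _ORACLE_MERGE.get(area, area)
    return ("contact", merged, best_hand, False)


@pytest.fixture
def table1():
    return TABLE1.copy()


@pytest.fixture
def table2():
    return TABLE2.copy()
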