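"""Head-sphere geometry, contact detection and area classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facetouch.gesture_detection import (
    DegenerateGeometryError,
    DetectorConfig,
    MissingJointError,
    classify_contact_area,
    compute_head_sphere,
    derive_mouth_point,
    detect_contact,
    face_landmarks,
    label_frame,
    merge_areas,
)
from facetouch.skeleton_io import JointName as J

from conftest import head_joints, make_frame, oracle_label_frame


# ---------------------------------------------------------------------------
# Head sphere


def test_head_sphere_from_simple_ears():
    f = make_frame({J.EAR_LEFT: (-75, 0, 0), J.EAR_RIGHT: (75, 0, 0)})
    s = compute_head_sphere(f)
    assert np.allclose(s.center, [0, 0, 0])
    assert s.head_radius == pytest.approx(75.0)
    assert s.contact_radius == pytest.approx(105.0)
    assert s.lowrisk_threshold == pytest.approx(112.5)
    assert s.lowrisk_threshold > s.contact_radius  # defaults ordering


@pytest.mark.parametrize(
    "head_breadth_cm,expected_contact_radius_cm",
    [(14.8, 10.36), (16.8, 11.76)],  # 5th / 95th percentile head breadth
)
def test_contact_radius_matches_anthropometric_range(head_breadth_cm, expected_contact_radius_cm):
    """70% of the inter-ear distance spans 10.36-11.76 cm across percentiles."""
    d_mm = head_breadth_cm * 10.0
    f = make_frame({J.EAR_LEFT: (d_mm / 2, 0, 0), J.EAR_RIGHT: (-d_mm / 2, 0, 0)})
    s = compute_head_sphere(f)
    assert s.contact_radius / 10.0 == pytest.approx(expected_contact_radius_cm, abs=1e-9)


def test_head_sphere_missing_ear_and_degenerate():
    with pytest.raises(MissingJointError):
        compute_head_sphere(make_frame({J.EAR_LEFT: (0, 0, 0)}))
    with pytest.raises(DegenerateGeometryError):
        compute_head_sphere(make_frame({J.EAR_LEFT: (1, 2, 3), J.EAR_RIGHT: (1, 2, 3)}))


# ---------------------------------------------------------------------------
# Mouth landmark


def test_mouth_point_upright_head():
    f = make_frame(
        {
            J.NOSE: (0, -40, -80),
            J.HEAD: (0, 0, 0),
            J.NECK: (0, 60, 0),
            J.EAR_LEFT: (75, 0, 0),
            J.EAR_RIGHT: (-75, 0, 0),
        }
    )
    assert np.allclose(derive_mouth_point(f), [0, -2.5, -80])


def test_mouth_point_falls_back_to_nose_without_neck():
    f = make_frame(
        {J.NOSE: (5, -40, -80), J.EAR_LEFT: (75, 0, 0), J.EAR_RIGHT: (-75, 0, 0)}
    )
    assert np.allclose(derive_mouth_point(f), [5, -40, -80])


def test_mouth_point_rotates_with_the_head():
    """Rigid rotation of all head joints rotates the mouth point identically."""
    joints = head_joints(center=(0, 0, 0), inter_ear=150.0)
    mouth0 = derive_mouth_point(make_frame(joints))
    theta = 0.7
    R = np.array(
        [
            [np.cos(theta), 0, np.sin(theta)],
            [0, 1, 0],
            [-np.sin(theta), 0, np.cos(theta)],
        ]
    )
    rotated = {n: R @ np.asarray(p, float) for n, p in joints.items()}
    assert np.allclose(derive_mouth_point(make_frame(rotated)), R @ mouth0, atol=1e-9)


# ---------------------------------------------------------------------------
# Contact detection


def test_contact_boundary_inclusive():
    joints = head_joints(center=(0, 0, 0), inter_ear=150.0)
    s = compute_head_sphere(make_frame(joints))
    at_center = make_frame({**joints, J.THUMB_RIGHT: (0, 0, 0)})
    assert detect_contact(at_center, s)[0] is True
    on_boundary = make_frame({**joints, J.THUMB_RIGHT: (s.contact_radius, 0, 0)})
    assert detect_contact(on_boundary, s)[0] is True  # inclusive
    outside = make_frame({**joints, J.THUMB_RIGHT: (2 * s.contact_radius, 0, 0)})
    assert detect_contact(outside, s)[0] is False


def test_contact_boundary_brute_force_grid():
    """Detector agrees with a plain distance check on a grid straddling the boundary."""
    joints = head_joints(center=(0, 0, 0), inter_ear=150.0)
    s = compute_head_sphere(make_frame(joints))
    for radius in np.linspace(0.9 * s.contact_radius, 1.1 * s.contact_radius, 21):
        for direction in np.eye(3):
            thumb = radius * direction
            f = make_frame({**joints, J.THUMB_RIGHT: thumb})
            expected = np.linalg.norm(thumb) <= s.contact_radius
            assert detect_contact(f, s)[0] == expected


def test_nearer_thumb_wins_when_both_tracked():
    joints = head_joints(center=(0, 0, 0), inter_ear=150.0)
    s = compute_head_sphere(make_frame(joints))
    f = make_frame({**joints, J.THUMB_RIGHT: (10, 0, 0), J.THUMB_LEFT: (50, 0, 0)})
    in_contact, hand, _ = detect_contact(f, s)
    assert in_contact and hand == "right"


def test_no_thumb_raises_missing_joint():
    joints = head_joints(center=(0, 0, 0), inter_ear=150.0)
    s = compute_head_sphere(make_frame(joints))
    with pytest.raises(MissingJointError):
        detect_contact(make_frame(joints), s)


# ---------------------------------------------------------------------------
# Area classification


def _sphere_and_landmarks(inter_ear=150.0):
    joints = head_joints(center=(0, 0, 0), inter_ear=inter_ear)
    frame = make_frame(joints)
    return compute_head_sphere(frame), face_landmarks(frame), joints


def test_thumb_on_nose_classifies_nose():
    s, lm, _ = _sphere_and_landmarks()
    assert classify_contact_area(lm.nose, lm, s) == "nose"


def test_low_risk_when_far_from_all_landmarks():
    """Thumb behind/above the head, inside the volume, beyond the threshold."""
    s, lm, _ = _sphere_and_landmarks()
    thumb = np.array([0.0, 60.0, 85.0])  # behind-below the head (+y down, +z back)
    distances = [np.linalg.norm(thumb - pos) for _, pos in lm.available()]
    assert np.linalg.norm(thumb - s.center) <= s.contact_radius
    assert all(d > s.lowrisk_threshold for d in distances)  # oracle: six distances
    assert classify_contact_area(thumb, lm, s) == "low_risk"


def test_tie_between_nose_and_eye_goes_to_nose():
    s, lm, _ = _sphere_and_landmarks()
    midpoint = 0.5 * (lm.nose + lm.right_eye)
    # brute-force check the tie, then the documented priority
    assert np.linalg.norm(midpoint - lm.nose) == pytest.approx(
        np.linalg.norm(midpoint - lm.right_eye)
    )
    assert classify_contact_area(midpoint, lm, s) == "nose"


def test_classification_over_available_landmark_subset():
    s, lm, _ = _sphere_and_landmarks()
    from facetouch.gesture_detection import FaceLandmarks

    only_ears = FaceLandmarks(right_ear=lm.right_ear, left_ear=lm.left_ear)
    assert classify_contact_area(lm.right_ear, only_ears, s) == "right_ear"
    empty = FaceLandmarks()
    assert classify_contact_area(lm.nose, empty, s) == "low_risk"


@pytest.mark.parametrize(
    "pre,post",
    [
        ("nose", "mouth_nose"),
        ("mouth", "mouth_nose"),
        ("right_eye", "right_eye"),
        ("left_eye", "left_eye"),
        ("right_ear", "right_ear"),
        ("left_ear", "left_ear"),
        ("low_risk", "low_risk"),
    ],
)
def test_merge_areas(pre, post):
    assert merge_areas(pre) == post


def test_merge_rejects_unknown_label():
    with pytest.raises(ValueError):
        merge_areas("forehead")


# ---------------------------------------------------------------------------
# label_frame composition and properties


def test_label_frame_far_thumb_no_contact():
    joints = head_joints(center=(0, 0, 2000.0), inter_ear=150.0)
    f = make_frame({**joints, J.THUMB_RIGHT: (0, 800, 1900)})
    label = label_frame(f)
    assert label.state == "no_contact" and label.area is None and not label.degraded


def test_label_frame_near_eye_contact():
    joints = head_joints(center=(0, 0, 2000.0), inter_ear=150.0)
    eye = joints[J.EYE_LEFT]
    f = make_frame({**joints, J.THUMB_RIGHT: eye + np.array([0, 5.0, 0])})
    # oracle: explicit distances to the six landmarks
    lm = face_landmarks(make_frame(joints))
    d_eye = 5.0
    others = [
        np.linalg.norm(eye + [0, 5.0, 0] - pos)
        for name, pos in lm.available()
        if name != "left_eye"
    ]
    assert all(d > d_eye for d in others)
    label = label_frame(f)
    assert (label.state, label.area, label.hand) == ("contact", "left_eye", "right")


def test_label_frame_degraded_when_not_processable():
    f = make_frame({J.EAR_LEFT: (75, 0, 0), J.EAR_RIGHT: (-75, 0, 0)})  # no thumbs
    label = label_frame(f)
    assert label.state == "no_contact" and label.degraded


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    thumb=st.tuples(*[st.floats(-250, 250) for _ in range(3)]),
    inter_ear=st.floats(120.0, 180.0),
    drop_eye=st.booleans(),
    drop_nose=st.booleans(),
)
def test_label_frame_equals_brute_force_oracle(thumb, inter_ear, drop_eye, drop_nose):
    """Random thumb positions in a 0.5 m cube around the head: full agreement
    with an independent straight-line implementation of the heuristics."""
    joints = head_joints(center=(0, 0, 0), inter_ear=inter_ear)
    if drop_eye:
        joints.pop(J.EYE_RIGHT)
    if drop_nose:
        joints.pop(J.NOSE)
    joints[J.THUMB_LEFT] = np.asarray(thumb, float)
    f = make_frame(joints)
    got = label_frame(f)
    state, area, hand, degraded = oracle_label_frame(f)
    assert (got.state, got.area, got.hand, got.degraded) == (state, area, hand, degraded)


def test_rigid_motion_invariance():
    """Translating + rotating every joint leaves state and area unchanged."""
    rng = np.random.default_rng(11)
    joints = head_joints(center=(0, 0, 0), inter_ear=157.0)
    joints[J.THUMB_RIGHT] = np.array([20.0, 30.0, -80.0])  # a contact frame
    base = label_frame(make_frame(joints))
    assert base.state == "contact"
    for _ in range(20):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        shift = rng.uniform(-500, 500, 3)
        moved = {n: R @ np.asarray(p, float) + shift for n, p in joints.items()}
        got = label_frame(make_frame(moved))
        assert (got.state, got.area) == (base.state, base.area)


@pytest.mark.parametrize("scale", [0.5, 1.0, 2.0, 7.3])
def test_scale_covariance(scale):
    """Scaling all coordinates by s > 0 leaves labels unchanged."""
    joints = head_joints(center=(40, -20, 1000), inter_ear=150.0)
    joints[J.THUMB_LEFT] = np.array([60.0, 40.0, 930.0])
    base = label_frame(make_frame(joints))
    scaled = {n: scale * np.asarray(p, float) for n, p in joints.items()}
    got = label_frame(make_frame(scaled))
    assert (got.state, got.area) == (base.state, base.area)


def test_radial_monotonicity_single_switch():
    """Moving the thumb radially outward flips contact -> no_contact at most once."""
    joints = head_joints(center=(0, 0, 0), inter_ear=150.0)
    direction = np.array([0.3, -0.5, -0.8])
    direction /= np.linalg.norm(direction)
    states = []
    for radius in np.linspace(0.0, 300.0, 121):
        f = make_frame({**joints, J.THUMB_RIGHT: radius * direction})
        states.append(label_frame(f).state)
    switches = sum(1 for a, b in zip(states, states[1:]) if a != b)
    assert states[0] == "contact" and switches <= 1


def test_within_thresholds_gets_landmark_label():
    """A thumb within the contact radius of the center and within the low-risk
    threshold of some landmark always gets a (merged) landmark label."""
    rng = np.random.default_rng(5)
    joints = head_joints(center=(0, 0, 0), inter_ear=150.0)
    frame = make_frame(joints)
    s = compute_head_sphere(frame)
    lm = face_landmarks(frame)
    hits = 0
    for _ in range(500):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = s.contact_radius * rng.uniform() ** (1 / 3)
        thumb = s.center + radius * direction  # uniform in the contact volume
        dists = [np.linalg.norm(thumb - pos) for _, pos in lm.available()]
        if min(dists) > s.lowrisk_threshold:
            continue
        hits += 1
        got = label_frame(make_frame({**joints, J.THUMB_LEFT: thumb}))
        assert got.state == "contact" and got.area != "low_risk"
    assert hits > 100  # the sample actually exercised the property


def test_custom_ratios_respected():
    joints = head_joints(center=(0, 0, 0), inter_ear=150.0)
    f = make_frame({**joints, J.THUMB_RIGHT: (0, 0, -140.0)})
    assert label_frame(f, DetectorConfig()).state == "no_contact"  # 140 > 105
    wide = DetectorConfig(contact_ratio=1.0, lowrisk_ratio=1.05)
    assert label_frame(f, wide).state == "contact"
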