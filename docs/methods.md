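# Methods

## Detection model

The detector is a pure per-frame geometric classifier on 32-joint skeletons
(positions in mm, right-handed camera space with x right, y down, z away from
the sensor; timestamps in seconds). For a frame with both ear joints tracked:

- head sphere: center `c` = midpoint of the ear joints, head radius = half
  the inter-ear distance `d`;
- contact volume: radius `contact_ratio · d`, default 0.70, tested against
  the nearest tracked thumb joint; the boundary is inclusive (distance equal
  to the threshold counts as contact) — the inclusive convention favors
  sensitivity toward risk contacts;
- area classification: nearest landmark among nose, mouth, right/left eye,
  right/left ear; if the nearest distance exceeds `lowrisk_ratio · d`
  (default 0.75, also inclusive on the landmark side) the contact is
  `low_risk`; mouth and nose then merge into `mouth_nose`.

Both ratios are configuration parameters; the defaults are empirical
trade-off values between false and missed contacts and are what all reported
numbers use. Because every threshold is proportional to `d`, labels are
invariant under rigid motion and under uniform scaling of all coordinates
(property-tested).

Choices where the geometry was open:

- **Mouth landmark.** The 32-joint skeleton has no mouth joint. The mouth is
  synthesized as `nose + 0.25·d·unit(neck − head)`, which sits below the nose
  along the head's longitudinal axis in any pose; with neck or head missing
  it falls back to the nose position. The stakes are low since mouth and nose
  merge into one class.
- **Thumb-only rule.** Hand and handtip joints are ignored; only thumbs are
  tested. With both thumbs tracked the one nearer the sphere center decides.
- **Raw landmarks.** Eye/ear landmarks are the raw joints, not projections
  onto the sphere surface.
- **Ties.** Equidistant landmarks are broken by fixed priority
  nose > mouth > right_eye > left_eye > right_ear > left_ear (a
  probability-zero event in real data, fixed for determinism).
- **Degraded frames.** A frame lacking both thumbs or either ear is labeled
  no-contact with `degraded = True` and counted in the report; the detector
  makes no attempt to interpolate through tracking loss.

## Event model and report

Contact events are exactly the run-length encoding of the per-frame
(state, area) sequence: no minimum duration, no gap merging by default (a
single contact frame is an event; jitter that splits a touch yields several
events — `min_frames` and `merge_gap_s` options exist but default to off, so
reported numbers reflect the raw label stream). An event's end is its last
contact frame's timestamp, so an n-frame event at fps f has duration
(n−1)/f; duration arithmetic in the report follows from that convention.

Interpersonal distance is the full 3D Euclidean distance between pelvis
joints, checked per frame across all tracked bodies against a 1000 mm
threshold; under-distance conditions stay per-frame alerts (with a count in
the report) rather than being grouped into events. Streaming use is supported
by `step()`, which emits `contact_started` / `area_changed` /
`contact_ended` signals on label transitions; accumulating those signals is
equivalent to batch grouping (property-tested).

## Evaluation protocol

Predicted events are matched to truth annotations greedily by descending
temporal overlap (ties: smaller midpoint distance, then earlier truth start),
each event used at most once; events without overlap may still match if
their midpoints are within a tolerance (default 0.5 s). The matching emulates
a manually synchronized video annotation rather than any published algorithm,
so it is deliberately simple and order-independent.

The confusion matrix is oriented rows = classifier, columns = truth —
deliberately matching the convention of the original validation tables and
the transpose of what scikit-learn produces. Three conventions matter:

- the classifier emits no occlusion label, so the occlusion **row** holds
  `no_detection` (nothing emitted); a truth occlusion correctly ignored lands
  on the diagonal, and a missed contact event lands in the occlusion row of
  its truth column;
- spurious predictions (no truth counterpart) are excluded from the matrix
  and reported separately, so the total equals the number of truth events;
- 0/0 metrics are NaN and flagged, never 0 or 100.

Cohen's κ uses the standard margins formula; κ is undefined (NaN) when all
mass lies in one row and one column. The Landis–Koch band is a plain label
lookup. The 7→3 clustering maps {mouth_nose, eyes} → risk contacts and
{ears, low_risk} → no-risk contacts, preserving totals by construction.

## Synthetic-data generator

The simulator emulates the validation scenario: one person standing 2 m from
a sensor mounted at 170 cm, facing it, executing scripted gestures at 30 fps.
Anthropometric presets carry the 5th/50th/95th percentile adult-male head
breadths (14.8 / 15.7 / 16.8 cm); the other preset dimensions (stature
164.5/175.6/186.6 cm, biacromial breadth 36.7/39.7/42.7 cm, arm length
70/75/80 cm) are standard anthropometric values of the same percentiles,
chosen once to pose a plausible static trunk.

Gesture kinematics are deliberately minimal — only the scripted thumb and its
wrist/hand/handtip chain move, on a piecewise-linear path (default 0.2 s
approach, 0.3 s hold): rest pose (hands at hip height, ~0.45 × stature below
the head) → a staging point on the ray from the head center through the
gesture's anchor, 180 mm outside the contact radius → radially inward to the
anchor. The radial final approach guarantees the thumb enters the contact
volume already nearest to its target landmark, so each scripted gesture
produces exactly one truth event of the scripted class. Anchors are:

- contact gestures: the target landmark offset 10 mm toward the head center
  (unambiguously inside the contact volume and the landmark's Voronoi cell);
- low-risk touches: a point behind the head at 0.95 × contact radius from
  the center — inside the volume, farther than the low-risk threshold from
  every landmark for all supported profiles;
- occlusions: a point on the sensor-to-head-center ray at 1.5 × contact
  radius — in front of the face in projection, outside the contact volume,
  so the detector sees nothing (the behavioral definition of an occlusion).

Ground truth derives from the noiseless trajectory: truth frame labels are
the detector's own output on the noise-free stream (contact events are its
run-length grouping), plus one truth `occlusion` event per occlusion gesture
spanning its hold window. Noise is then applied only to the emitted frames:
isotropic Gaussian jitter per joint per frame (default sd 5 mm — real
trackers jitter visibly near the face but the magnitude is small against the
≥100 mm contact radius) and independent dropout of face/thumb joints. All
randomness flows from one seeded generator, so identical seeds give
byte-identical streams.

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: biomechanically realistic arm paths, head rotation and
torso motion, correlated or depth-dependent tracking error, systematic joint
misplacement when fingers are near the face (the dominant real-world failure
mode), multi-person occlusion, or frame drops. Results on synthetic streams
bound the pipeline's logic, not the sensor's tracking quality.

Multi-body streams place single-body streams at the vertices of a regular
polygon with the requested side length in the floor plane (pairwise distances
are exactly the separation for two or three bodies) and reassign body ids.

## Numerical and serialization choices

- Millimeters internally everywhere; configuration in cm is converted at the
  boundary. Timestamps are float seconds; the detector assumes no frame rate
  (purely per-frame), only the simulator does (default 30 fps).
- Stream serialization writes positions at 0.001 mm and timestamps at 1 µs
  precision, with joints in a fixed canonical order, so output is
  byte-stable and round-trips exactly for values at that precision.
- Degenerate inputs: coincident ears raise a geometry error; empty label
  buffers give a zero report; an empty confusion matrix is an error rather
  than a silent NaN set.
- The scale-consistency property across anthropometric presets is asserted on
  the truth *event label sequence*, not per-frame runs: presets do not scale
  the whole body uniformly, so the frame at which the approach path crosses
  the contact threshold can shift by a frame between profiles, while the
  event sequence is invariant.

## Test problem sizes

The suite exercises the detector against an independently written
straight-line oracle on 10⁴ random frames, the streaming/batch equivalence
and clustering identities on randomized sequences/matrices, noiseless
recovery (κ = 1) across all three presets, a jitter sweep
(0/5/15/40 mm × 20 seeds) for the graceful-degradation trend, and a
scaled-down end-to-end validation run of 60 events across the seven truth
classes at 5 mm jitter, where only structural properties (vocabulary,
total conservation, κ > 0.5) are asserted because the run is stochastic.
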