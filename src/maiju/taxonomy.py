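"""Category taxonomies for the infant motor-ability description scheme.

Three parallel annotation tracks describe each second of a recording:

* posture   -- the gross body configuration (7 classes, incl. two
               intermediate side-lying classes),
* movement  -- the quality of movement within the posture (4 graded
               qualities plus 5 intermediate types),
* carrying  -- whether the infant moves independently or is supported /
               carried by an adult (5 classes).

Left/right intermediate categories are fused for recording-level
distribution features (``FUSED_*``), matching the convention used for
motor-ability trajectory summaries.
"""

from __future__ import annotations

POSTURES: tuple[str, ...] = (
    "supine",
    "prone",
    "side_left",
    "side_right",
    "crawl_posture",
    "sitting",
    "standing",
)

MOVEMENTS: tuple[str, ...] = (
    "still",
    "proto",
    "elementary",
    "fluent",
    "pivot_left",
    "pivot_right",
    "roll_left",
    "roll_right",
    "transition",
)

CARRYING: tuple[str, ...] = (
    "independent",
    "passive_support",
    "active_support",
    "passive_carry",
    "active_carry",
)

TRACKS: dict[str, tuple[str, ...]] = {
    "posture": POSTURES,
    "movement": MOVEMENTS,
    "carrying": CARRYING,
}

#: Label used for seconds/frames with no annotation; encoded as -1.
UNLABELED = "unlabeled"
UNLABELED_CODE = -1

# Fused (left/right-collapsed) category sets used for recording-level
# motor-ability distributions.
FUSED_POSTURES: tuple[str, ...] = (
    "supine",
    "prone",
    "side",
    "crawl_posture",
    "sitting",
    "standing",
)

FUSED_MOVEMENTS: tuple[str, ...] = (
    "still",
    "proto",
    "elementary",
    "fluent",
    "pivot",
    "roll",
    "transition",
)

POSTURE_FUSE_MAP: dict[str, str] = {
    "supine": "supine",
    "prone": "prone",
    "side_left": "side",
    "side_right": "side",
    "crawl_posture": "crawl_posture",
    "sitting": "sitting",
    "standing": "standing",
}

MOVEMENT_FUSE_MAP: dict[str, str] = {
    "still": "still",
    "proto": "proto",
    "elementary": "elementary",
    "fluent": "fluent",
    "pivot_left": "pivot",
    "pivot_right": "pivot",
    "roll_left": "roll",
    "roll_right": "roll",
    "transition": "transition",
}

SENSORS: tuple[str, ...] = ("left_arm", "right_arm", "left_leg", "right_leg")

#: Nominal IMU sampling rate (Hz).
SAMPLE_RATE = 52.0

#: Frame geometry: 120-sample (~2.3 s) frames with 50% overlap.
FRAME_LEN = 120
FRAME_HOP = 60

#: Standard gravity (m/s^2).
GRAVITY = 9.81


def encode(labels, classes) -> "list[int]":
    """Map label strings to integer codes (``UNLABELED`` -> -1)."""
    index = {c: i for i, c in enumerate(classes)}
    index[UNLABELED] = UNLABELED_CODE
    return [index[lab] for lab in labels]


def decode(codes, classes) -> "list[str]":
    """Map integer codes back to label strings."""
    return [UNLABELED if c == UNLABELED_CODE else classes[c] for c in codes]
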