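"""Gaze-direction labels and conventions shared across modules.

All geometry lives in a single viewer-fixed, right-handed frame:
x = rightward, y = upward, z = out of the image toward the camera.
Angles are in degrees, counterclockwise from +x, reported in [0, 360).

Ductions are sampled along four meridians (horizontal, vertical, two
diagonals), giving eight eccentric gaze labels plus ``primary``.
Anatomical duction names (adduction, supraduction, ...) are resolved per
eye at the labeling layer; the math below only ever sees these
viewer-fixed labels.
"""

from __future__ import annotations

PRIMARY = "primary"

#: The eight eccentric gaze labels, counterclockwise from rightward gaze.
GAZE_LABELS: tuple[str, ...] = (
    "right",
    "up_right",
    "up",
    "up_left",
    "left",
    "down_left",
    "down",
    "down_right",
)

#: Nominal meridian direction for each gaze label (deg CCW from +x).
NOMINAL_DIRECTION_DEG: dict[str, float] = {
    label: 45.0 * i for i, label in enumerate(GAZE_LABELS)
}

#: Label of the mirror gaze about the vertical axis (x -> -x). Used to
#: pair "matching ductions" between the eyes: the right eye's rightward
#: gaze engages the same muscle pair as the left eye's leftward gaze.
MIRROR_LABEL: dict[str, str] = {
    "right": "left",
    "left": "right",
    "up_right": "up_left",
    "up_left": "up_right",
    "down_right": "down_left",
    "down_left": "down_right",
    "up": "up",
    "down": "down",
}

ALL_GAZE_LABELS: tuple[str, ...] = (PRIMARY,) + GAZE_LABELS

EYES: tuple[str, str] = ("OD", "OS")


def wrap_direction(angle_deg: float) -> float:
    """Map an angle to [0, 360)."""
    return float(angle_deg) % 360.0


def wrap_signed(angle_deg: float) -> float:
    """Map an angular difference to the minimal arc in (-180, 180]."""
    return -((-float(angle_deg) + 180.0) % 360.0 - 180.0)
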