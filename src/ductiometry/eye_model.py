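"""Biometric eye model, unit conversions, and the forward projection map.

The eye is modeled as a rigid globe rotating about a fixed center of
rotation. The limbus (corneal-scleral boundary) is a planar ring sitting
a fixed axial distance in front of that center; ocular rotations move
the ring in 3D and the camera records its orthographic projection. This
module owns everything on the *forward* side of that picture:

* the biometric constants (center-of-rotation depth, corneal sagittal
  depth, horizontal visible iris diameter) and their consistency checks;
* pixel-to-millimeter conversion calibrated on the primary-gaze limbus;
* head-translation correction (shift coordinates opposite a measured
  displacement);
* least-squares ellipse fitting of the primary-gaze boundary and its
  3D embedding as the reference ring;
* the axis-angle (Rodrigues) rotation of that ring, with axes confined
  to Listing's plane, and the orthographic projection back to 2D;
* confusion-matrix metrics for scoring third-party segmentation masks.

The inverse problem — recovering the rotation from an observed eccentric
boundary — lives in :mod:`ductiometry.rotation`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation
from skimage.measure import EllipseModel

from .directions import ALL_GAZE_LABELS, EYES

__all__ = [
    "BiometricModel",
    "LimbusBoundary",
    "ReferenceEllipse",
    "MaskMetrics",
    "EllipseFitError",
    "fit_reference_ellipse",
    "pixels_to_mm",
    "correct_head_translation",
    "rotate_embedding",
    "rotate_points",
    "project",
    "mask_metrics",
    "tangent_screen_rope_length",
    "max_duction_from_screen",
]


class EllipseFitError(ValueError):
    """Raised when an ellipse cannot be fit through boundary points."""


@dataclass(frozen=True)
class BiometricModel:
    """Population-average ocular biometrics used by the forward model.

    Parameters
    ----------
    limbus_to_center_distance_mm
        Axial distance from the limbus plane to the eye's center of
        rotation. Default 10.45 mm.
    corneal_sagittal_depth_mm
        Height of the corneal cap in front of the limbus plane.
        Default 2.5 mm.
    apex_to_center_distance_mm
        Distance from the corneal apex to the center of rotation; must
        equal the sum of the two terms above. Default 12.95 mm.
    horizontal_visible_iris_diameter_mm
        HVID, the calibration length for pixel-to-mm conversion.
        Default 11.75 mm.
    viewing_distance_cm
        Fixation-target distance used by the recording protocol.
        Default 40 cm.
    """

    limbus_to_center_distance_mm: float = 10.45
    corneal_sagittal_depth_mm: float = 2.5
    apex_to_center_distance_mm: float = 12.95
    horizontal_visible_iris_diameter_mm: float = 11.75
    viewing_distance_cm: float = 40.0

    def __post_init__(self) -> None:
        lengths = (
            self.limbus_to_center_distance_mm,
            self.corneal_sagittal_depth_mm,
            self.apex_to_center_distance_mm,
            self.horizontal_visible_iris_diameter_mm,
            self.viewing_distance_cm,
        )
        if any(not (v > 0) for v in lengths):
            raise ValueError("all biometric lengths must be strictly positive")
        expected = self.corneal_sagittal_depth_mm + self.limbus_to_center_distance_mm
        if abs(self.apex_to_center_distance_mm - expected) > 1e-9:
            raise ValueError(
                "apex_to_center_distance_mm must equal corneal_sagittal_depth_mm"
                f" + limbus_to_center_distance_mm ({expected!r}), got"
                f" {self.apex_to_center_distance_mm!r}"
            )

    @property
    def limbus_radius_mm(self) -> float:
        return self.horizontal_visible_iris_diameter_mm / 2.0


@dataclass(frozen=True)
class LimbusBoundary:
    """An ordered ring of 2D limbus boundary points for one frame.

    ``points`` is an (n, 2) array in the order traced around the ring;
    the ring is implicitly closed (last point connects back to first).
    ``mm_per_px`` records the conversion factor once the boundary has
    been converted from pixels.
    """

    points: np.ndarray
    units: str
    participant_id: str
    eye: str
    gaze_label: str
    frame_index: int
    mm_per_px: Optional[float] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if pts.shape[0] < 5:
            raise ValueError("at least 5 points are required to determine an ellipse")
        if not np.all(np.isfinite(pts)):
            raise ValueError("boundary points must be finite")
        object.__setattr__(self, "points", pts)
        if self.units not in ("px", "mm"):
            raise ValueError(f"units must be 'px' or 'mm', got {self.units!r}")
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        if self.gaze_label not in ALL_GAZE_LABELS:
            raise ValueError(f"unknown gaze_label {self.gaze_label!r}")

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def is_simple_ring(self) -> bool:
        """True if the closed ring does not self-intersect."""
        from shapely.geometry import LinearRing

        try:
            return bool(LinearRing(self.points).is_simple)
        except Exception:
            return False


@dataclass(frozen=True)
class ReferenceEllipse:
    """Fitted primary-gaze ellipse and its 3D embedding.

    The embedding places the fitted 2D ring in an eye-centered frame
    whose origin is the center of rotation: the ring is planar, centered
    on the optical (z) axis at z = +limbus_to_center_distance, and its
    orthographic projection reproduces the fitted 2D shape. ``center``
    keeps the fitted ellipse center in the original image coordinates so
    observed boundaries can be expressed in the same eye-centered frame.
    """

    center: np.ndarray
    semi_major_mm: float
    semi_minor_mm: float
    tilt_deg: float
    embedding: np.ndarray
    residual_rms_mm: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(2)
        object.__setattr__(self, "center", c)
        emb = np.asarray(self.embedding, dtype=float)
        if emb.ndim != 2 or emb.shape[1] != 3:
            raise ValueError("embedding must be an (n, 3) array")
        object.__setattr__(self, "embedding", emb)
        if not (self.semi_major_mm >= self.semi_minor_mm > 0):
            raise ValueError("require semi_major >= semi_minor > 0")

    @property
    def ring2d(self) -> np.ndarray:
        """The embedded ring's own orthographic projection (centered)."""
        return self.embedding[:, :2]


def fit_reference_ellipse(
    boundary: LimbusBoundary,
    model: BiometricModel,
    n_ring: int = 360,
) -> ReferenceEllipse:
    """Fit the primary-gaze reference ellipse and embed it in 3D.

    A direct least-squares conic fit (with ellipse constraint) is run
    through the boundary points; the fitted shape, re-centered on the
    optical axis, is embedded as a planar ring at
    z = ``limbus_to_center_distance_mm``.

    Parameters
    ----------
    boundary
        Primary-gaze boundary in millimeters.
    model
        Biometric constants supplying the embedding depth.
    n_ring
        Number of parametric samples on the embedded ring.

    Raises
    ------
    EllipseFitError
        If the points are degenerate (e.g. collinear) or the conic fit
        does not yield a real ellipse.
    """
    if boundary.units != "mm":
        raise ValueError("reference boundary must be in mm (convert from px first)")
    fit = EllipseModel.from_estimate(boundary.points)
    if not fit:
        raise EllipseFitError(f"ellipse fit failed: {fit}")
    cx, cy = (float(v) for v in fit.center)
    a, b = (float(v) for v in fit.axis_lengths)
    tilt = math.degrees(float(fit.theta))
    if b > a:
        a, b = b, a
        tilt += 90.0
    tilt %= 180.0
    if not (b > 0) or not np.isfinite([cx, cy, a, b]).all():
        raise EllipseFitError("degenerate ellipse fit")
    residual = float(np.sqrt(np.mean(fit.residuals(boundary.points) ** 2)))

    t = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
    tr = math.radians(tilt)
    x = a * np.cos(t) * math.cos(tr) - b * np.sin(t) * math.sin(tr)
    y = a * np.cos(t) * math.sin(tr) + b * np.sin(t) * math.cos(tr)
    z = np.full(n_ring, model.limbus_to_center_distance_mm)
    return ReferenceEllipse(
        center=np.array([cx, cy]),
        semi_major_mm=a,
        semi_minor_mm=b,
        tilt_deg=tilt,
        embedding=np.c_[x, y, z],
        residual_rms_mm=residual,
    )


def pixels_to_mm(
    boundary: LimbusBoundary,
    reference_px_width: float,
    model: Optional[BiometricModel] = None,
) -> LimbusBoundary:
    """Convert a pixel-space boundary to millimeters.

    The conversion factor is HVID divided by the horizontal pixel width
    of the participant's primary-gaze limbus, so one factor per
    participant calibrates every frame.
    """
    if boundary.units != "px":
        raise ValueError("boundary is not in px")
    if not reference_px_width > 0:
        raise ValueError("reference_px_width must be positive")
    model = model or BiometricModel()
    factor = model.horizontal_visible_iris_diameter_mm / reference_px_width
    return replace(
        boundary, points=boundary.points * factor, units="mm", mm_per_px=factor
    )


def correct_head_translation(
    boundary: LimbusBoundary, displacement_mm: np.ndarray
) -> LimbusBoundary:
    """Shift limbus coordinates opposite a measured head displacement.

    Counteracts the intrusion of head translations into the limbus
    coordinates; only translations (not head rotations) are corrected.
    """
    if boundary.units != "mm":
        raise ValueError("head-translation correction expects mm coordinates")
    d = np.asarray(displacement_mm, dtype=float).reshape(2)
    return replace(boundary, points=boundary.points - d)


def rotate_points(points3d: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate 3D points about an axis in Listing's plane through the origin.

    The axis must have zero z-component (no torsion); it is normalized
    to unit length before the Rodrigues rotation is applied.
    """
    axis = np.asarray(axis, dtype=float).reshape(3)
    if abs(axis[2]) > 1e-9:
        raise ValueError("rotation axis must lie in Listing's plane (z component = 0)")
    norm = float(np.linalg.norm(axis))
    if norm == 0.0:
        if angle_deg == 0.0:
            return np.asarray(points3d, dtype=float).copy()
        raise ValueError("zero-length axis with nonzero angle")
    rot = Rotation.from_rotvec(axis / norm * math.radians(angle_deg))
    return np.asarray(points3d, dtype=float) @ rot.as_matrix().T


def rotate_embedding(
    ellipse: ReferenceEllipse, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rotate a reference ellipse's embedded ring by an axis-angle pair."""
    if not (abs(angle_deg) <= 180.0):
        raise ValueError("|angle| must be <= 180 degrees")
    return rotate_points(ellipse.embedding, axis, angle_deg)


def project(points3d: np.ndarray) -> np.ndarray:
    """Orthographic projection onto the image plane: drop the z coordinate."""
    pts = np.asarray(points3d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) array")
    return pts[:, :2].copy()


@dataclass(frozen=True)
class MaskMetrics:
    """Confusion-matrix scores for a binary segmentation mask.

    Ratios with a zero denominator are ``None`` (undefined), never
    silently 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: Optional[float] = field(init=False)
    sensitivity: Optional[float] = field(init=False)
    specificity: Optional[float] = field(init=False)
    precision: Optional[float] = field(init=False)

    def __post_init__(self) -> None:
        def ratio(num: int, den: int) -> Optional[float]:
            return num / den if den > 0 else None

        object.__setattr__(self, "accuracy", ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn))
        object.__setattr__(self, "sensitivity", ratio(self.tp, self.tp + self.fn))
        object.__setattr__(self, "specificity", ratio(self.tn, self.tn + self.fp))
        object.__setattr__(self, "precision", ratio(self.tp, self.tp + self.fp))


def mask_metrics(predicted_mask: np.ndarray, truth_mask: np.ndarray) -> MaskMetrics:
    """Score a predicted binary mask against a ground-truth mask.

    accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP); precision = TP/(TP+FP).
    """
    pred = np.asarray(predicted_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must share dimensions")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return MaskMetrics(tp=tp, tn=tn, fp=fp, fn=fn)


def tangent_screen_rope_length(
    viewing_distance_cm: float, max_duction_deg: float
) -> float:
    """Full meridian rope length for a tangent screen.

    A rope spanning both senses of a meridian must extend
    ``viewing_distance * tan(max_duction)`` on each side of center.
    """
    return 2.0 * viewing_distance_cm * math.tan(math.radians(max_duction_deg))


def max_duction_from_screen(
    half_extent_cm: float, viewing_distance_cm: float
) -> float:
    """Eccentricity (deg) subtended by a half-meridian of the screen."""
    return math.degrees(math.atan2(half_extent_cm, viewing_distance_cm))
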