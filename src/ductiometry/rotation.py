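"""Axis-angle rotation estimation from observed limbus boundaries.

Inverts the forward model in :mod:`ductiometry.eye_model`: given the
primary-gaze reference ellipse and an eccentric boundary, a
derivative-free simplex search finds the axis (in Listing's plane) and
angle whose forward projection best matches the observation. Matching
uses a polar-correspondence error: both rings are resampled at equally
spaced polar angles about the observed ring's centroid and same-angle
distances are summed.

Also provides least-error estimate selection (keep the k best frames
per duction) and conversion of an estimate to a duction vector
(magnitude @ direction in the image plane).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .directions import wrap_direction
from .eye_model import LimbusBoundary, ReferenceEllipse, project, rotate_points

__all__ = [
    "RotationEstimate",
    "DuctionVector",
    "EstimateOptions",
    "StarShapeError",
    "correspondence_error",
    "resample_polar",
    "estimate_rotation",
    "select_least_error",
    "select_per_duction",
    "to_duction_vector",
]

AXIS_BOUND = 1.0
THETA_MIN, THETA_MAX = 0.0, 90.0
_PENALTY = 1e9


class StarShapeError(ValueError):
    """A ring is not star-shaped about the resampling center."""


@dataclass(frozen=True)
class RotationEstimate:
    """One fitted ocular rotation.

    ``param1``/``param2`` are the Listing's-plane axis components (the
    axes about which vertical and horizontal rotations occur,
    respectively); ``theta_deg`` is the rotation angle. Only the axis
    direction is meaningful — it is normalized before use.
    """

    param1: float
    param2: float
    theta_deg: float
    error: float
    converged: bool = True
    n_iterations: int = 0
    participant_id: Optional[str] = None
    eye: Optional[str] = None
    gaze_label: Optional[str] = None
    frame_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not (-AXIS_BOUND <= self.param1 <= AXIS_BOUND):
            raise ValueError("param1 out of [-1, 1]")
        if not (-AXIS_BOUND <= self.param2 <= AXIS_BOUND):
            raise ValueError("param2 out of [-1, 1]")
        if not (THETA_MIN <= self.theta_deg <= THETA_MAX):
            raise ValueError("theta out of [0, 90] degrees")
        if not (self.error >= 0):
            raise ValueError("error must be non-negative")

    @property
    def axis(self) -> np.ndarray:
        """Unit rotation axis in Listing's plane."""
        v = np.array([self.param1, self.param2, 0.0])
        n = np.linalg.norm(v)
        return v / n if n > 0 else v


@dataclass(frozen=True)
class DuctionVector:
    """A duction expressed as magnitude (deg) @ direction (deg CCW from +x).

    ``direction_deg`` is ``None`` for a zero-magnitude duction, whose
    direction is undefined.
    """

    magnitude_deg: float
    direction_deg: Optional[float]
    label: str
    eye: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.magnitude_deg <= 90.0):
            raise ValueError("magnitude must be in [0, 90] degrees")
        if self.direction_deg is not None:
            object.__setattr__(
                self, "direction_deg", wrap_direction(self.direction_deg)
            )

    @property
    def xy(self) -> np.ndarray:
        """Cartesian tip of the vector (deg units in the gaze plane)."""
        if self.direction_deg is None:
            return np.zeros(2)
        d = math.radians(self.direction_deg)
        return self.magnitude_deg * np.array([math.cos(d), math.sin(d)])


def _winding_deg(points: np.ndarray, center: np.ndarray) -> float:
    rel = points - center
    ang = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    d = np.diff(np.r_[ang, ang[0]])
    d = (d + 180.0) % 360.0 - 180.0
    return float(d.sum())


def resample_polar(
    points: np.ndarray, center: np.ndarray, n_samples: int
) -> np.ndarray:
    """Radii of a ring at equally spaced polar angles about ``center``.

    Raises :class:`StarShapeError` when the ring does not wind exactly
    once around the center (polar resampling would be multivalued).
    """
    points = np.asarray(points, dtype=float)
    center = np.asarray(center, dtype=float).reshape(2)
    if abs(abs(_winding_deg(points, center)) - 360.0) > 1.0:
        raise StarShapeError(
            "ring does not wind exactly once about the resampling center;"
            " polar correspondence is undefined"
        )
    rel = points - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    rad = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(ang, kind="stable")
    targets = 2.0 * np.pi * np.arange(n_samples) / n_samples - np.pi
    return np.interp(targets, ang[order], rad[order], period=2.0 * np.pi)


def correspondence_error(
    estimated_ring: np.ndarray,
    observed_ring: np.ndarray,
    n_samples: int = 360,
) -> float:
    """Total same-angle distance between two rings.

    Both rings are resampled at ``n_samples`` equally spaced polar
    angles about the *observed* ring's centroid; the error is the sum
    over samples of the Euclidean distance between same-angle points
    (which reduces to the absolute radius difference along each ray).
    """
    observed_ring = np.asarray(observed_ring, dtype=float)
    center = observed_ring.mean(axis=0)
    r_obs = resample_polar(observed_ring, center, n_samples)
    r_est = resample_polar(np.asarray(estimated_ring, dtype=float), center, n_samples)
    return float(np.abs(r_obs - r_est).sum())


@dataclass(frozen=True)
class EstimateOptions:
    """Tuning knobs for the simplex search."""

    n_samples: int = 360
    n_restarts: int = 4
    restart_seed: int = 0
    maxiter: int = 600
    xatol: float = 1e-4
    fatol: float = 1e-7
    theta_jitter_deg: float = 5.0
    axis_jitter_deg: float = 20.0


def _clamp(p: np.ndarray) -> tuple[np.ndarray, float]:
    clamped = np.array(
        [
            min(max(p[0], -AXIS_BOUND), AXIS_BOUND),
            min(max(p[1], -AXIS_BOUND), AXIS_BOUND),
            min(max(p[2], THETA_MIN), THETA_MAX),
        ]
    )
    violation = float(np.abs(p - clamped).sum())
    return clamped, violation


def _forward_ring(
    reference: ReferenceEllipse, p1: float, p2: float, theta: float
) -> Optional[np.ndarray]:
    axis = np.array([p1, p2, 0.0])
    if np.linalg.norm(axis) < 1e-12:
        if theta < 1e-9:
            return reference.ring2d
        return None
    return project(rotate_points(reference.embedding, axis, theta))


def estimate_rotation(
    reference: ReferenceEllipse,
    observed: LimbusBoundary,
    opts: EstimateOptions = EstimateOptions(),
) -> RotationEstimate:
    """Estimate the rotation carrying the reference onto an observation.

    Runs a bounded Nelder-Mead search over (param1, param2, theta);
    each iteration forward-projects the rotated reference ring and
    scores it with :func:`correspondence_error` against the observed
    boundary expressed in the eye-centered frame. The search starts
    from a chord-angle initial guess (axis perpendicular to the
    centroid displacement) plus seeded jittered restarts, and the best
    minimum is kept. Bounds are enforced by clamping inside the
    objective with an out-of-bounds penalty.
    """
    if observed.units != "mm":
        raise ValueError("observed boundary must be in mm")
    obs = observed.points - reference.center

    def objective(p: np.ndarray) -> float:
        clamped, violation = _clamp(p)
        ring = _forward_ring(reference, *clamped)
        if ring is None:
            return _PENALTY
        try:
            err = correspondence_error(ring, obs, opts.n_samples)
        except StarShapeError:
            return _PENALTY
        return err + _PENALTY * violation

    # Chord-based initial guess: the ring center sits a known radius
    # from the center of rotation, so the projected centroid
    # displacement bounds the rotation angle via the chord formula.
    disp = obs.mean(axis=0) - reference.ring2d.mean(axis=0)
    chord = float(np.linalg.norm(disp))
    radius = float(np.linalg.norm(reference.embedding.mean(axis=0)))
    theta0 = (
        math.degrees(2.0 * math.asin(min(chord / (2.0 * radius), 1.0)))
        if radius > 0
        else 0.0
    )
    theta0 = min(max(theta0, THETA_MIN), THETA_MAX)
    if chord > 1e-12:
        u = disp / chord
        axis0 = np.array([-u[1], u[0]])
    else:
        axis0 = np.array([0.0, 1.0])

    rng = np.random.default_rng(opts.restart_seed)
    starts = [np.array([axis0[0], axis0[1], theta0])]
    for _ in range(opts.n_restarts):
        rot = math.radians(rng.normal(0.0, opts.axis_jitter_deg))
        c, s = math.cos(rot), math.sin(rot)
        jittered_axis = np.array([c * axis0[0] - s * axis0[1], s * axis0[0] + c * axis0[1]])
        jt = min(max(theta0 + rng.normal(0.0, opts.theta_jitter_deg), THETA_MIN), THETA_MAX)
        starts.append(np.array([jittered_axis[0], jittered_axis[1], jt]))

    best = None
    total_iters = 0
    any_converged = False
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": opts.maxiter,
                "xatol": opts.xatol,
                "fatol": opts.fatol,
            },
        )
        total_iters += int(res.nit)
        if best is None or res.fun < best.fun:
            best = res
            any_converged = bool(res.success)
        elif res.fun == best.fun and res.success:
            any_converged = True
    assert best is not None
    p, _ = _clamp(best.x)
    return RotationEstimate(
        param1=float(p[0]),
        param2=float(p[1]),
        theta_deg=float(p[2]),
        error=float(objective(p)),
        converged=any_converged,
        n_iterations=total_iters,
        participant_id=observed.participant_id,
        eye=observed.eye,
        gaze_label=observed.gaze_label,
        frame_index=observed.frame_index,
    )


def select_least_error(
    estimates: Sequence[RotationEstimate], k: int = 3
) -> list[RotationEstimate]:
    """Keep the ``k`` estimates with smallest residual error.

    Ties break by ascending frame index for reproducibility. Applied
    per duction so every duction stays represented in downstream means.
    If fewer than ``k`` estimates are supplied, all are returned with a
    warning.
    """
    if len(estimates) < k:
        warnings.warn(
            f"only {len(estimates)} estimates available; expected >= {k}",
            stacklevel=2,
        )
        k = len(estimates)
    ranked = sorted(
        estimates,
        key=lambda e: (e.error, e.frame_index if e.frame_index is not None else 0),
    )
    return ranked[:k]


def select_per_duction(
    estimates: Sequence[RotationEstimate], k: int = 3
) -> list[RotationEstimate]:
    """Apply :func:`select_least_error` within each (participant, eye, duction)."""
    groups: dict[tuple, list[RotationEstimate]] = {}
    for e in estimates:
        groups.setdefault((e.participant_id, e.eye, e.gaze_label), []).append(e)
    selected: list[RotationEstimate] = []
    for key in sorted(groups, key=lambda t: tuple(str(x) for x in t)):
        selected.extend(select_least_error(groups[key], k=k))
    return selected


def to_duction_vector(
    estimate: RotationEstimate, eye: Optional[str] = None
) -> DuctionVector:
    """Convert a rotation estimate to a duction vector.

    Magnitude is the rotation angle; direction is the polar angle of
    the projected displacement of the limbus-ring center under the
    estimated axis-angle pair. A zero-angle rotation has no defined
    direction and maps to the null vector.
    """
    eye = eye or estimate.eye
    if eye is None:
        raise ValueError("eye must be provided")
    label = estimate.gaze_label or ""
    if estimate.theta_deg == 0.0:
        return DuctionVector(0.0, None, label=label, eye=eye)
    a = estimate.axis
    if np.linalg.norm(a) == 0.0:
        return DuctionVector(0.0, None, label=label, eye=eye)
    # Center starts on the optical axis at (0, 0, 1)*depth; its projected
    # displacement under a Listing's-plane rotation is sin(theta)*(ay, -ax).
    direction = math.degrees(math.atan2(-a[0], a[1]))
    return DuctionVector(
        magnitude_deg=estimate.theta_deg,
        direction_deg=direction,
        label=label,
        eye=eye,
    )
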