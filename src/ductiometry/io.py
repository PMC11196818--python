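"""Reading, validation, and serialization of pipeline interchange files.

CSV is the canonical interchange format: one boundary row per point,
one estimate row per frame. JSON carries reports and YAML carries
configuration. Schema validation is strict and names the offending
rows — a malformed file should fail loudly before any geometry runs.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from shapely.geometry import LinearRing

from .eye_model import LimbusBoundary
from .rotation import RotationEstimate, to_duction_vector
from .simulate import GroundTruthRotation

__all__ = [
    "SchemaError",
    "BOUNDARY_COLUMNS",
    "read_boundaries",
    "write_boundaries",
    "boundaries_to_frame",
    "estimates_to_frame",
    "frame_to_estimates",
    "write_estimates",
    "read_estimates",
    "truths_to_frame",
    "write_truths",
    "read_displacements",
]

BOUNDARY_COLUMNS = (
    "participant_id",
    "eye",
    "gaze_label",
    "frame_index",
    "point_index",
    "x",
    "y",
    "units",
)


class SchemaError(ValueError):
    """An interchange file violates the expected schema."""


def boundaries_to_frame(boundaries: Iterable[LimbusBoundary]) -> pd.DataFrame:
    rows = []
    for b in boundaries:
        for i, (x, y) in enumerate(b.points):
            rows.append(
                (b.participant_id, b.eye, b.gaze_label, b.frame_index, i, x, y, b.units)
            )
    return pd.DataFrame(rows, columns=list(BOUNDARY_COLUMNS))


def write_boundaries(boundaries: Iterable[LimbusBoundary], path) -> None:
    boundaries_to_frame(boundaries).to_csv(path, index=False)


def read_boundaries(
    path, y_down: bool = False, check_simple: bool = True
) -> list[LimbusBoundary]:
    """Load and validate a boundary CSV.

    Parameters
    ----------
    path
        CSV with columns ``participant_id, eye, gaze_label,
        frame_index, point_index, x, y, units``; one ring per
        (participant, eye, gaze_label, frame_index).
    y_down
        Set for files in image-row convention (y increases downward);
        the y axis is flipped on load so all downstream geometry uses
        y-up coordinates.
    check_simple
        Reject rings that self-intersect.

    Raises
    ------
    SchemaError
        On missing columns, duplicate point keys, inconsistent units
        within a frame, too-few points, or non-ring geometry; messages
        name the offending frame or rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in BOUNDARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    key_cols = ["participant_id", "eye", "gaze_label", "frame_index", "point_index"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        rows = (df.index[dup][:5] + 2).tolist()  # 1-based incl. header
        raise SchemaError(f"{path}: duplicate point keys at file rows {rows}")
    boundaries: list[LimbusBoundary] = []
    group_cols = ["participant_id", "eye", "gaze_label", "frame_index"]
    for (pid, eye, gaze, frame), grp in df.groupby(group_cols, sort=True):
        grp = grp.sort_values("point_index")
        units = grp["units"].unique()
        if len(units) != 1:
            raise SchemaError(
                f"{path}: mixed units {units.tolist()} in frame "
                f"({pid}, {eye}, {gaze}, {frame})"
            )
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        if y_down:
            pts = pts * np.array([1.0, -1.0])
        frame_id = f"({pid}, {eye}, {gaze}, {frame})"
        if pts.shape[0] < 5:
            raise SchemaError(f"{path}: frame {frame_id} has fewer than 5 points")
        if not np.all(np.isfinite(pts)):
            raise SchemaError(f"{path}: non-finite coordinates in frame {frame_id}")
        if check_simple and not LinearRing(pts).is_simple:
            raise SchemaError(f"{path}: frame {frame_id} is not a simple ring")
        try:
            boundaries.append(
                LimbusBoundary(
                    points=pts,
                    units=str(units[0]),
                    participant_id=str(pid),
                    eye=str(eye),
                    gaze_label=str(gaze),
                    frame_index=int(frame),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: frame {frame_id}: {exc}") from exc
    return boundaries


ESTIMATE_COLUMNS = (
    "participant_id",
    "eye",
    "gaze_label",
    "frame_index",
    "param1",
    "param2",
    "theta_deg",
    "direction_deg",
    "error",
    "converged",
    "n_iterations",
)


def estimates_to_frame(estimates: Iterable[RotationEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        vec = to_duction_vector(e) if e.eye is not None else None
        rows.append(
            (
                e.participant_id,
                e.eye,
                e.gaze_label,
                e.frame_index,
                e.param1,
                e.param2,
                e.theta_deg,
                None if vec is None else vec.direction_deg,
                e.error,
                e.converged,
                e.n_iterations,
            )
        )
    return pd.DataFrame(rows, columns=list(ESTIMATE_COLUMNS))


def write_estimates(estimates: Iterable[RotationEstimate], path) -> None:
    estimates_to_frame(estimates).to_csv(path, index=False)


def frame_to_estimates(df: pd.DataFrame) -> list[RotationEstimate]:
    missing = [c for c in ESTIMATE_COLUMNS[:10] if c not in df.columns]
    if missing:
        raise SchemaError(f"estimates table missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            RotationEstimate(
                param1=float(row.param1),
                param2=float(row.param2),
                theta_deg=float(row.theta_deg),
                error=float(row.error),
                converged=bool(row.converged),
                n_iterations=int(getattr(row, "n_iterations", 0) or 0),
                participant_id=str(row.participant_id),
                eye=str(row.eye),
                gaze_label=str(row.gaze_label),
                frame_index=int(row.frame_index),
            )
        )
    return out


def read_estimates(path) -> list[RotationEstimate]:
    return frame_to_estimates(pd.read_csv(path))


TRUTH_COLUMNS = (
    "participant_id",
    "eye",
    "gaze_label",
    "frame_index",
    "angle_deg",
    "direction_deg",
    "axis_x",
    "axis_y",
    "head_dx_mm",
    "head_dy_mm",
)


def truths_to_frame(truths: Iterable[GroundTruthRotation]) -> pd.DataFrame:
    rows = [
        (
            t.participant_id,
            t.eye,
            t.gaze_label,
            t.frame_index,
            t.angle_deg,
            t.direction_deg,
            t.axis[0],
            t.axis[1],
            t.head_displacement_mm[0],
            t.head_displacement_mm[1],
        )
        for t in truths
    ]
    return pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))


def write_truths(truths: Iterable[GroundTruthRotation], path) -> None:
    truths_to_frame(truths).to_csv(path, index=False)


def read_displacements(path) -> dict[tuple, np.ndarray]:
    """Per-frame head displacements keyed by (participant, eye, gaze, frame).

    Accepts a truth CSV or any table with the key columns plus
    ``head_dx_mm`` / ``head_dy_mm``.
    """
    df = pd.read_csv(path)
    needed = ["participant_id", "eye", "gaze_label", "frame_index", "head_dx_mm", "head_dy_mm"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return {
        (str(r.participant_id), str(r.eye), str(r.gaze_label), int(r.frame_index)): np.array(
            [float(r.head_dx_mm), float(r.head_dy_mm)]
        )
        for r in df.itertuples(index=False)
    }
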