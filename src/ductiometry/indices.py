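"""Summary indices of ocular motility patterns.

A participant's eight ductions per eye are condensed into:

* **Motor fields** (MF_OD, MF_OS) — the polygonal area enclosed by the
  duction tips, optionally normalized by the cohort mean so values
  center about 1.
* **Discrepancies** (MDisc, GDisc) — the proportion of non-overlapping
  ("monocular only") area when the two motor fields are superimposed,
  after reflecting the left eye's field about the vertical axis (motor,
  comparing matching ductions) or as-is (gaze, comparing matching gaze
  directions). Bounded in [0, 1]: 0 at complete overlap, 1 when
  disjoint.
* **Muscle biases** (MB_OD, MB_OS) — the vector average of one eye's
  ductions after normalizing by the largest magnitude; a pro/anti
  dipole pointing toward the largest/smallest movements.
* **Muscle / gaze differences** (MDiff, GDiff) — dipoles built from
  per-duction interocular difference vectors (with / without the
  vertical-axis reflection), pointing toward where the eyes differ
  most/least.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

from .directions import GAZE_LABELS, MIRROR_LABEL, NOMINAL_DIRECTION_DEG, wrap_direction
from .rotation import DuctionVector

__all__ = [
    "DuctionSet",
    "MotorFieldResult",
    "DiscrepancyResult",
    "BiasDipole",
    "IndexReport",
    "motor_field",
    "motor_field_polygon",
    "normalize_motor_fields",
    "discrepancy",
    "discrepancy_from_polygons",
    "muscle_bias",
    "muscle_difference",
    "gaze_difference",
    "build_index_report",
    "build_cohort_reports",
]

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class DuctionSet:
    """Eight labeled duction vectors for one eye of one participant."""

    participant_id: str
    eye: str
    vectors: Mapping[str, DuctionVector]

    def __post_init__(self) -> None:
        labels = set(self.vectors)
        if labels != set(GAZE_LABELS):
            raise ValueError(
                f"a DuctionSet needs exactly the 8 gaze labels; got {sorted(labels)}"
            )
        for label, v in self.vectors.items():
            if v.label != label:
                raise ValueError(f"vector labeled {v.label!r} stored under {label!r}")
        object.__setattr__(self, "vectors", dict(self.vectors))

    def tips(self) -> np.ndarray:
        """Duction tips ordered CCW by direction angle (simple polygon)."""
        rows = []
        for label in GAZE_LABELS:
            v = self.vectors[label]
            ang = (
                v.direction_deg
                if v.direction_deg is not None
                else NOMINAL_DIRECTION_DEG[label]
            )
            rows.append((ang, v.xy))
        rows.sort(key=lambda r: r[0])
        return np.array([xy for _, xy in rows])

    def magnitudes(self) -> np.ndarray:
        return np.array([self.vectors[l].magnitude_deg for l in GAZE_LABELS])


@dataclass(frozen=True)
class MotorFieldResult:
    raw_area_deg2: float
    normalized: Optional[float]
    polygon: np.ndarray


@dataclass(frozen=True)
class DiscrepancyResult:
    """Proportion of monocular-only area between superimposed motor fields."""

    value: float
    kind: str
    monocular_polygons: tuple = ()

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.value <= 1.0 + 1e-12):
            raise ValueError("discrepancy must lie in [0, 1]")
        object.__setattr__(self, "value", float(min(max(self.value, 0.0), 1.0)))
        if self.kind not in ("motor", "gaze"):
            raise ValueError("kind must be 'motor' or 'gaze'")


@dataclass(frozen=True)
class BiasDipole:
    """A pro/anti vector pair; anti is always the negation of pro.

    For difference dipoles, ``mean_raw_norm`` keeps the mean magnitude
    of the *un-normalized* difference vectors (deg). The pro/anti
    magnitudes are scale-invariant by construction, so this is the
    quantity that carries the absolute size of interocular differences.
    """

    pro: np.ndarray
    kind: str
    mean_raw_norm: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pro", np.asarray(self.pro, dtype=float).reshape(2))

    @property
    def anti(self) -> np.ndarray:
        return -self.pro

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.pro))

    @property
    def direction_deg(self) -> Optional[float]:
        """Direction of the pro vector; None for a zero dipole."""
        if self.magnitude <= _ZERO_TOL:
            return None
        return wrap_direction(math.degrees(math.atan2(self.pro[1], self.pro[0])))

    def to_dict(self) -> dict:
        return {
            "magnitude": self.magnitude,
            "direction_deg": self.direction_deg,
            "pro": [float(self.pro[0]), float(self.pro[1])],
            "kind": self.kind,
            "mean_raw_norm": self.mean_raw_norm,
        }


def _polygon(tips: np.ndarray) -> Polygon:
    poly = Polygon(np.asarray(tips, dtype=float))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def motor_field_polygon(ductions: DuctionSet) -> np.ndarray:
    """Vertex ring (deg) of the motor-field polygon."""
    return ductions.tips()


def motor_field(ductions: DuctionSet) -> float:
    """Raw motor-field area (deg^2) enclosed by the duction tips."""
    tips = ductions.tips()
    area = _polygon(tips).area
    if not area > 0:
        raise ValueError("degenerate motor field: duction tips enclose no area")
    return float(area)


def normalize_motor_fields(raw_areas: Iterable[float]) -> np.ndarray:
    """Express each raw motor field relative to the cohort mean.

    Centering about 1 replaces non-intuitive deg^2 units; the cohort
    mean of the returned values is exactly 1.
    """
    areas = np.asarray(list(raw_areas), dtype=float)
    if areas.size == 0:
        raise ValueError("no areas supplied")
    if np.any(areas <= 0):
        raise ValueError("all raw areas must be positive")
    return areas / areas.mean()


def _reflect(points: np.ndarray) -> np.ndarray:
    out = np.asarray(points, dtype=float).copy()
    out[:, 0] *= -1.0
    return out


def discrepancy_from_polygons(
    od_tips: np.ndarray, os_tips: np.ndarray, kind: str
) -> DiscrepancyResult:
    """Discrepancy between two motor-field vertex rings.

    For ``kind='motor'`` the OS ring is reflected about the vertical
    axis first. The value is area(symmetric difference) divided by the
    sum of both polygon areas.
    """
    if kind not in ("motor", "gaze"):
        raise ValueError("kind must be 'motor' or 'gaze'")
    os_ring = _reflect(os_tips) if kind == "motor" else np.asarray(os_tips, float)
    p_od = _polygon(od_tips)
    p_os = _polygon(os_ring)
    if not (p_od.area > 0 and p_os.area > 0):
        raise ValueError("degenerate polygon in discrepancy computation")
    sym = p_od.symmetric_difference(p_os)
    value = sym.area / (p_od.area + p_os.area)
    pieces = tuple(
        np.asarray(g.exterior.coords)
        for g in getattr(sym, "geoms", [sym])
        if g.area > 0 and g.geom_type == "Polygon"
    )
    return DiscrepancyResult(value=value, kind=kind, monocular_polygons=pieces)


def discrepancy(od: DuctionSet, os: DuctionSet, kind: str) -> DiscrepancyResult:
    """Motor or gaze discrepancy between a participant's two eyes."""
    return discrepancy_from_polygons(od.tips(), os.tips(), kind)


def muscle_bias(ductions: DuctionSet) -> BiasDipole:
    """Intraocular asymmetry dipole of one eye's ductions.

    Vectors are normalized by the largest magnitude and vector-averaged;
    the magnitude is 0 for equal opposing ductions and 1 when all
    ductions point the same way.
    """
    vecs = np.array([ductions.vectors[l].xy for l in GAZE_LABELS])
    norms = np.linalg.norm(vecs, axis=1)
    if norms.max() <= 0:
        raise ValueError("all-zero duction set has no defined muscle bias")
    pro = (vecs / norms.max()).mean(axis=0)
    kind = f"muscle_bias_{ductions.eye}"
    return BiasDipole(pro=pro, kind=kind)


def _sign0(x: float) -> float:
    # sign with sign(0) := +1 so zero components never flip orientation
    return 1.0 if x >= 0 else -1.0


def _difference_dipole(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]], kind: str
) -> BiasDipole:
    diffs = []
    for od_xy, os_xy in pairs:
        dx = abs(od_xy[0] - os_xy[0]) * _sign0(od_xy[0])
        dy = abs(od_xy[1] - os_xy[1]) * _sign0(od_xy[1])
        diffs.append((dx, dy))
    diffs_arr = np.asarray(diffs, dtype=float)
    norms = np.linalg.norm(diffs_arr, axis=1)
    max_norm = float(norms.max())
    if max_norm <= _ZERO_TOL:
        # identical eyes: the normalization limit is a zero dipole
        return BiasDipole(pro=np.zeros(2), kind=kind, mean_raw_norm=0.0)
    pro = (diffs_arr / max_norm).mean(axis=0)
    return BiasDipole(pro=pro, kind=kind, mean_raw_norm=float(norms.mean()))


def muscle_difference(od: DuctionSet, os: DuctionSet) -> BiasDipole:
    """Interocular difference dipole comparing matching ductions.

    The left eye's vectors are reflected about the vertical axis so a
    muscle pair (e.g. both lateral recti) is compared; differences are
    componentwise absolute values signed by the right eye's components,
    normalized by the largest difference magnitude, then averaged.
    """
    pairs = []
    for label in GAZE_LABELS:
        od_xy = od.vectors[label].xy
        os_xy = os.vectors[MIRROR_LABEL[label]].xy
        os_xy = np.array([-os_xy[0], os_xy[1]])
        pairs.append((od_xy, os_xy))
    return _difference_dipole(pairs, "muscle_difference")


def gaze_difference(od: DuctionSet, os: DuctionSet) -> BiasDipole:
    """Interocular difference dipole comparing matching gaze directions.

    Identical to :func:`muscle_difference` except the left eye's
    vectors are not reflected.
    """
    pairs = [
        (od.vectors[label].xy, os.vectors[label].xy) for label in GAZE_LABELS
    ]
    return _difference_dipole(pairs, "gaze_difference")


@dataclass(frozen=True)
class IndexReport:
    """The full index framework for one participant."""

    participant_id: str
    mf_od: MotorFieldResult
    mf_os: MotorFieldResult
    mdisc: DiscrepancyResult
    gdisc: DiscrepancyResult
    mb_od: BiasDipole
    mb_os: BiasDipole
    mdiff: BiasDipole
    gdiff: BiasDipole

    def to_dict(self) -> dict:
        def mf(m: MotorFieldResult) -> dict:
            return {
                "raw_deg2": float(m.raw_area_deg2),
                "normalized": None if m.normalized is None else float(m.normalized),
            }

        return {
            "participant_id": self.participant_id,
            "MF_OD": mf(self.mf_od),
            "MF_OS": mf(self.mf_os),
            "MDisc": float(self.mdisc.value),
            "GDisc": float(self.gdisc.value),
            "MB_OD": self.mb_od.to_dict(),
            "MB_OS": self.mb_os.to_dict(),
            "MDiff": self.mdiff.to_dict(),
            "GDiff": self.gdiff.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def build_index_report(
    od: DuctionSet,
    os: DuctionSet,
    normative_mf_means: Optional[Mapping[str, float]] = None,
) -> IndexReport:
    """Bundle all indices for one participant into a serializable report.

    ``normative_mf_means`` maps eye -> cohort mean raw motor field used
    for normalization; when omitted the normalized fields are ``None``
    (use :func:`build_cohort_reports` to normalize within a cohort).
    """
    if od.participant_id != os.participant_id:
        raise ValueError("both eyes must belong to the same participant")
    if (od.eye, os.eye) != ("OD", "OS"):
        raise ValueError("expected (OD, OS) duction sets")
    raw = {"OD": motor_field(od), "OS": motor_field(os)}
    normalized = {"OD": None, "OS": None}
    if normative_mf_means is not None:
        for eye in ("OD", "OS"):
            mean = float(normative_mf_means[eye])
            if not mean > 0:
                raise ValueError("normative motor-field mean must be positive")
            normalized[eye] = raw[eye] / mean
    return IndexReport(
        participant_id=od.participant_id,
        mf_od=MotorFieldResult(raw["OD"], normalized["OD"], od.tips()),
        mf_os=MotorFieldResult(raw["OS"], normalized["OS"], os.tips()),
        mdisc=discrepancy(od, os, "motor"),
        gdisc=discrepancy(od, os, "gaze"),
        mb_od=muscle_bias(od),
        mb_os=muscle_bias(os),
        mdiff=muscle_difference(od, os),
        gdiff=gaze_difference(od, os),
    )


def build_cohort_reports(
    pairs: Sequence[tuple[DuctionSet, DuctionSet]]
) -> list[IndexReport]:
    """Index reports for a cohort, normalizing motor fields per eye.

    Each eye's raw areas are divided by that eye's cohort mean, so the
    cohort mean of the normalized motor fields is exactly 1 per eye.
    """
    if not pairs:
        raise ValueError("empty cohort")
    means = {
        "OD": float(np.mean([motor_field(od) for od, _ in pairs])),
        "OS": float(np.mean([motor_field(os) for _, os in pairs])),
    }
    return [build_index_report(od, os, means) for od, os in pairs]
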