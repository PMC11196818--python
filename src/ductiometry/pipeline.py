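"""End-to-end orchestration: simulate -> estimate -> indices -> mdc -> report.

Every stage is a plain function over the library modules; this module
adds configuration, stage-tagged error handling, record-count logging,
and a :class:`RunManifest` that makes end-to-end determinism checkable
(identical manifest implies byte-identical outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .change import MDCResult, mdc95, sem_from_rmanova
from .directions import GAZE_LABELS, NOMINAL_DIRECTION_DEG, PRIMARY, wrap_signed
from .eye_model import (
    BiometricModel,
    LimbusBoundary,
    ReferenceEllipse,
    correct_head_translation,
    fit_reference_ellipse,
    pixels_to_mm,
)
from .indices import DuctionSet, build_cohort_reports
from .rotation import (
    DuctionVector,
    EstimateOptions,
    RotationEstimate,
    estimate_rotation,
    select_per_duction,
    to_duction_vector,
)
from .simulate import SimulationConfig, simulate_boundaries_dataset
from . import io as dio

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "RunManifest",
    "PipelineResult",
    "run_pipeline",
    "estimate_boundaries",
    "selected_vectors_by_participant",
    "duction_sets_from_selection",
    "duction_mdc",
    "index_mdc",
]

logger = logging.getLogger("ductiometry")


class PipelineStageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full simulated run.

    ``seed`` drives the simulation; MDC resampling uses a sub-seed
    derived deterministically from it.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    select_k: int = 3
    n_samples: int = 360
    n_restarts: int = 2
    mdc_iters: int = 200
    y_down: bool = False

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def estimate_options(self) -> EstimateOptions:
        return EstimateOptions(
            n_samples=self.n_samples,
            n_restarts=self.n_restarts,
            restart_seed=self.seed % (2**31),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["biometrics"] = asdict(self.simulation.biometrics)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        bio = sim.pop("biometrics", None)
        if bio is not None:
            sim["biometrics"] = BiometricModel(**bio)
        return cls(simulation=SimulationConfig(**sim), **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record for one pipeline run."""

    tool_version: str
    seed: int
    config_hash: str
    input_checksums: dict
    counts: dict

    def to_dict(self) -> dict:
        return {
            "tool_version": self.tool_version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "input_checksums": dict(sorted(self.input_checksums.items())),
            "counts": dict(sorted(self.counts.items())),
        }


def _ellipse_px_width(boundary: LimbusBoundary) -> float:
    """Horizontal width of the fitted reference limbus, in the boundary's units."""
    from skimage.measure import EllipseModel

    fit = EllipseModel.from_estimate(boundary.points)
    if not fit:
        raise ValueError("cannot fit reference ellipse for width calibration")
    a, b = (float(v) for v in fit.axis_lengths)
    th = float(fit.theta)
    return 2.0 * math.sqrt((a * math.cos(th)) ** 2 + (b * math.sin(th)) ** 2)


def estimate_boundaries(
    boundaries: Sequence[LimbusBoundary],
    biometrics: BiometricModel = BiometricModel(),
    opts: EstimateOptions = EstimateOptions(),
    displacements: Optional[Mapping[tuple, np.ndarray]] = None,
    select_k: Optional[int] = None,
) -> tuple[list[RotationEstimate], dict[tuple, ReferenceEllipse]]:
    """Estimate rotations for every eccentric frame.

    Groups frames per (participant, eye), fits the primary-gaze
    reference (converting px to mm against the primary limbus width if
    needed), applies head-translation corrections when supplied, and
    runs the rotation estimator on each eccentric frame. When
    ``select_k`` is given, only the k least-error estimates per duction
    are returned.
    """
    groups: dict[tuple, list[LimbusBoundary]] = {}
    for b in boundaries:
        groups.setdefault((b.participant_id, b.eye), []).append(b)

    estimates: list[RotationEstimate] = []
    references: dict[tuple, ReferenceEllipse] = {}
    for key in sorted(groups):
        frames = groups[key]
        primaries = [b for b in frames if b.gaze_label == PRIMARY]
        if not primaries:
            raise ValueError(f"no primary-gaze frame for {key}; cannot calibrate")
        primary = min(primaries, key=lambda b: b.frame_index)
        mm_per_px = None
        if primary.units == "px":
            width_px = _ellipse_px_width(primary)
            mm_per_px = biometrics.horizontal_visible_iris_diameter_mm / width_px

        def to_mm(b: LimbusBoundary) -> LimbusBoundary:
            if b.units == "mm":
                return b
            if mm_per_px is None:
                raise ValueError(
                    f"frame {(b.participant_id, b.eye, b.gaze_label, b.frame_index)}"
                    " is in px but no primary-gaze reference width is available"
                )
            return pixels_to_mm(b, biometrics.horizontal_visible_iris_diameter_mm / mm_per_px, biometrics)

        def corrected(b: LimbusBoundary) -> LimbusBoundary:
            b = to_mm(b)
            if displacements is not None:
                d = displacements.get(
                    (b.participant_id, b.eye, b.gaze_label, b.frame_index)
                )
                if d is not None:
                    b = correct_head_translation(b, d)
            return b

        reference = fit_reference_ellipse(corrected(primary), biometrics)
        references[key] = reference
        for b in frames:
            if b.gaze_label == PRIMARY:
                continue
            estimates.append(estimate_rotation(reference, corrected(b), opts))
    if select_k is not None:
        estimates = select_per_duction(estimates, k=select_k)
    return estimates, references


def selected_vectors_by_participant(
    estimates: Sequence[RotationEstimate],
) -> dict[str, dict[tuple[str, str], list[DuctionVector]]]:
    """Group estimates as duction vectors: pid -> (eye, label) -> vectors."""
    out: dict[str, dict[tuple[str, str], list[DuctionVector]]] = {}
    for e in estimates:
        vec = to_duction_vector(e)
        out.setdefault(e.participant_id, {}).setdefault((e.eye, e.gaze_label), []).append(vec)
    return out


def _mean_vector(vectors: Sequence[DuctionVector], label: str, eye: str) -> DuctionVector:
    mag = float(np.mean([v.magnitude_deg for v in vectors]))
    nominal = NOMINAL_DIRECTION_DEG[label]
    offsets = [
        wrap_signed((v.direction_deg if v.direction_deg is not None else nominal) - nominal)
        for v in vectors
    ]
    return DuctionVector(mag, nominal + float(np.mean(offsets)), label=label, eye=eye)


def duction_sets_from_selection(
    vectors: Mapping[str, Mapping[tuple[str, str], Sequence[DuctionVector]]],
) -> list[tuple[DuctionSet, DuctionSet]]:
    """Per-participant (OD, OS) duction sets averaging selected frames."""
    pairs = []
    for pid in sorted(vectors):
        per_eye = {}
        for eye in ("OD", "OS"):
            vecs = {}
            for label in GAZE_LABELS:
                pool = vectors[pid].get((eye, label))
                if not pool:
                    raise ValueError(f"participant {pid} missing {eye} {label} estimates")
                vecs[label] = _mean_vector(pool, label, eye)
            per_eye[eye] = DuctionSet(pid, eye, vecs)
        pairs.append((per_eye["OD"], per_eye["OS"]))
    return pairs


def duction_mdc(
    vectors: Mapping[str, Mapping[tuple[str, str], Sequence[DuctionVector]]],
    n_iter: int,
    seed: int,
    model: str = "two_way",
) -> dict[str, MDCResult]:
    """MDC distributions for duction magnitude and direction.

    One resampled distribution per (eye, duction) combination, as in
    the 16-matrix scheme; directions are resampled on the wrapped
    offset from each duction's nominal meridian.
    """
    from .change import resample_mdc

    out: dict[str, MDCResult] = {}
    for eye in ("OD", "OS"):
        for label in GAZE_LABELS:
            mag_pools = {}
            dir_pools = {}
            for pid in sorted(vectors):
                pool = vectors[pid].get((eye, label), [])
                mag_pools[pid] = [v.magnitude_deg for v in pool]
                nominal = NOMINAL_DIRECTION_DEG[label]
                dir_pools[pid] = [
                    nominal + wrap_signed((v.direction_deg or nominal) - nominal)
                    for v in pool
                ]
            sub = int(hashlib.sha256(f"{seed}:{eye}:{label}".encode()).hexdigest(), 16) % (2**31)
            out[f"duction_magnitude_{eye}_{label}"] = resample_mdc(
                mag_pools, n_iter=n_iter, seed=sub, model=model,
                metric_name=f"duction_magnitude_{eye}_{label}", units="deg",
            )
            out[f"duction_direction_{eye}_{label}"] = resample_mdc(
                dir_pools, n_iter=n_iter, seed=sub + 1, model=model,
                metric_name=f"duction_direction_{eye}_{label}", units="deg",
            )
    return out


INDEX_METRICS = ("MF_OD", "MF_OS", "MDisc", "GDisc", "MB_OD", "MB_OS", "MDiff", "GDiff")


def _index_values(pairs: Sequence[tuple[DuctionSet, DuctionSet]]) -> dict[str, np.ndarray]:
    reports = build_cohort_reports(list(pairs))
    return {
        "MF_OD": np.array([r.mf_od.normalized for r in reports]),
        "MF_OS": np.array([r.mf_os.normalized for r in reports]),
        "MDisc": np.array([r.mdisc.value for r in reports]),
        "GDisc": np.array([r.gdisc.value for r in reports]),
        "MB_OD": np.array([r.mb_od.magnitude for r in reports]),
        "MB_OS": np.array([r.mb_os.magnitude for r in reports]),
        "MDiff": np.array([r.mdiff.magnitude for r in reports]),
        "GDiff": np.array([r.gdiff.magnitude for r in reports]),
    }


def index_mdc(
    vectors: Mapping[str, Mapping[tuple[str, str], Sequence[DuctionVector]]],
    n_iter: int,
    seed: int,
    model: str = "two_way",
) -> dict[str, MDCResult]:
    """MDC distributions for every summary index.

    Each iteration draws, twice per participant, one rotation estimate
    per duction, computes all indices for the drawn cohorts, and runs
    one repeated-measures ANOVA per index on the resulting N x 2
    matrices. All indices share the iteration's draws.
    """
    rng = np.random.default_rng(seed)
    pids = sorted(vectors)

    def draw_pair(pid: str) -> tuple[DuctionSet, DuctionSet]:
        per_eye = {}
        for eye in ("OD", "OS"):
            vecs = {}
            for label in GAZE_LABELS:
                pool = list(vectors[pid][(eye, label)])
                vecs[label] = pool[int(rng.integers(0, len(pool)))]
            per_eye[eye] = DuctionSet(pid, eye, vecs)
        return per_eye["OD"], per_eye["OS"]

    draws: dict[str, list[float]] = {m: [] for m in INDEX_METRICS}
    for _ in range(n_iter):
        occ_a = _index_values([draw_pair(pid) for pid in pids])
        occ_b = _index_values([draw_pair(pid) for pid in pids])
        for m in INDEX_METRICS:
            matrix = np.c_[occ_a[m], occ_b[m]]
            draws[m].append(mdc95(sem_from_rmanova(matrix, model=model)))
    units = {"MF_OD": "unitless", "MF_OS": "unitless"}
    return {
        m: MDCResult(np.array(draws[m]), metric_name=m, units=units.get(m, "unitless"))
        for m in INDEX_METRICS
    }


@dataclass(frozen=True)
class PipelineResult:
    manifest: RunManifest
    boundaries: list
    truths: list
    estimates: list
    selected: list
    reports: list
    mdc: dict

    def report_dict(self) -> dict:
        return {
            "manifest": self.manifest.to_dict(),
            "participants": [r.to_dict() for r in self.reports],
            "mdc": {k: v.to_dict() for k, v in sorted(self.mdc.items())},
        }

    def report_json(self) -> str:
        return json.dumps(self.report_dict(), sort_keys=True, indent=1)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_boundaries(self.boundaries, out / "boundaries.csv")
        dio.write_truths(self.truths, out / "truth.csv")
        dio.write_estimates(self.estimates, out / "estimates.csv")
        dio.write_estimates(self.selected, out / "selected.csv")
        (out / "report.json").write_text(self.report_json())


def run_pipeline(
    config: PipelineConfig, out_dir=None, include_index_mdc: bool = True
) -> PipelineResult:
    """Run the full simulated pipeline and return all stage outputs.

    Stages run in order (simulate, estimate, select, indices, mdc) with
    record-count logging; any failure aborts with a stage-tagged error.
    """

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # fail fast with stage context
            raise PipelineStageError(name, exc) from exc
        return result

    counts: dict[str, int] = {}

    def run_simulate():
        boundaries, truths = simulate_boundaries_dataset(config.simulation)
        return boundaries, truths

    boundaries, truths = stage("simulate", run_simulate)
    counts["n_participants"] = config.simulation.cohort_size
    counts["n_frames"] = len(boundaries)
    counts["frames_per_participant"] = config.simulation.frames_per_participant
    logger.info("simulate: %d frames", len(boundaries))

    displacements = {
        (t.participant_id, t.eye, t.gaze_label, t.frame_index): t.head_displacement_mm
        for t in truths
    }

    def run_estimate():
        return estimate_boundaries(
            boundaries,
            config.simulation.biometrics,
            config.estimate_options(),
            displacements=displacements,
        )

    estimates, _references = stage("estimate", run_estimate)
    counts["n_estimates"] = len(estimates)
    logger.info("estimate: %d rotations", len(estimates))

    def run_select():
        return select_per_duction(estimates, k=config.select_k)

    selected = stage("select", run_select)
    counts["n_selected"] = len(selected)
    counts["selected_per_participant"] = (
        len(selected) // config.simulation.cohort_size
    )
    logger.info("select: kept %d rotations", len(selected))

    def run_indices():
        vectors = selected_vectors_by_participant(selected)
        pairs = duction_sets_from_selection(vectors)
        return vectors, build_cohort_reports(pairs)

    vectors, reports = stage("indices", run_indices)
    counts["n_reports"] = len(reports)
    logger.info("indices: %d participant reports", len(reports))

    def run_mdc():
        if len(vectors) < 2:
            logger.info("mdc: skipped (needs >= 2 participants)")
            return {}
        mdc_seed = int(
            hashlib.sha256(f"mdc:{config.seed}".encode()).hexdigest(), 16
        ) % (2**31)
        results = duction_mdc(vectors, n_iter=config.mdc_iters, seed=mdc_seed)
        if include_index_mdc and len(vectors) >= 2:
            results.update(
                index_mdc(vectors, n_iter=config.mdc_iters, seed=mdc_seed + 1)
            )
        return results

    mdc = stage("mdc", run_mdc)
    counts["n_mdc_metrics"] = len(mdc)
    logger.info("mdc: %d metrics", len(mdc))

    manifest = RunManifest(
        tool_version=__version__,
        seed=config.seed,
        config_hash=config.config_hash(),
        input_checksums={},
        counts=counts,
    )
    result = PipelineResult(
        manifest=manifest,
        boundaries=boundaries,
        truths=truths,
        estimates=estimates,
        selected=selected,
        reports=reports,
        mdc=mdc,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
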