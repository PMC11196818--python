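"""Forward simulation of limbus boundaries and normative duction cohorts.

Stands in for recorded data: ground-truth rotations are drawn from a
normative anisotropic profile (adduction and adducted-depression
largest, elevation smallest), pushed through the forward
rotation-plus-projection model, and degraded with the imaging artifacts
the estimation pipeline must tolerate — isotropic boundary point noise,
a missing (occluded) arc of the ring, and small head translations.
Ground truth is always emitted alongside the simulated data so
downstream estimates can be scored.

Two granularities are offered: frame-level boundary simulation (feeds
the full estimation pipeline) and vector-level cohort simulation
(duction vectors with between-/within-subject variability, feeding the
index and MDC machinery directly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .directions import GAZE_LABELS, MIRROR_LABEL, NOMINAL_DIRECTION_DEG, PRIMARY
from .eye_model import BiometricModel, LimbusBoundary, ReferenceEllipse, project, rotate_points
from .rotation import DuctionVector

__all__ = [
    "SimulationConfig",
    "GroundTruthRotation",
    "CohortDataset",
    "ParticipantVectors",
    "reference_from_biometrics",
    "axis_for_direction",
    "simulate_boundary",
    "simulate_participant_frames",
    "simulate_boundaries_dataset",
    "simulate_cohort",
]


def _default_profile() -> dict[str, float]:
    # Normative OD magnitudes (deg) per viewer-fixed gaze label. For the
    # right eye "left" is adduction (largest, with the adducted-depressed
    # diagonal close behind) and "up" is elevation (smallest); the
    # overall mean sits near 39-40 deg.
    return {
        "right": 38.0,
        "up_right": 35.0,
        "up": 31.3,
        "up_left": 38.0,
        "left": 46.6,
        "down_left": 42.4,
        "down": 42.0,
        "down_right": 40.0,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the normative recording design: 20 participants,
    5 frames per duction (82 frames per participant including the two
    primary-gaze frames), within-subject repeat noise of 1.6 deg
    (placing duction-magnitude MDCs in the 4-8 deg band), and
    millimeter-scale imaging artifacts.
    """

    biometrics: BiometricModel = field(default_factory=BiometricModel)
    cohort_size: int = 20
    duction_mean_profile: dict[str, float] = field(default_factory=_default_profile)
    between_subject_sd: float = 4.0
    within_subject_sd: float = 1.6
    direction_jitter_sd: float = 4.0
    interocular_asymmetry_sd: float = 1.0
    boundary_noise_sd: float = 0.05
    occlusion_fraction: float = 0.2
    head_translation_sd: float = 0.3
    frames_per_duction: int = 5
    n_boundary_points: int = 180
    seed: int = 0

    def __post_init__(self) -> None:
        sds = (
            self.between_subject_sd,
            self.within_subject_sd,
            self.direction_jitter_sd,
            self.interocular_asymmetry_sd,
            self.boundary_noise_sd,
            self.head_translation_sd,
        )
        if any(s < 0 for s in sds):
            raise ValueError("all noise SDs must be >= 0")
        if not (0.0 <= self.occlusion_fraction < 0.5):
            raise ValueError("occlusion_fraction must lie in [0, 0.5)")
        if self.cohort_size < 1 or self.frames_per_duction < 1:
            raise ValueError("cohort_size and frames_per_duction must be >= 1")
        if self.n_boundary_points < 10:
            raise ValueError("n_boundary_points must be >= 10")
        if set(self.duction_mean_profile) != set(GAZE_LABELS):
            raise ValueError("duction_mean_profile must cover the 8 gaze labels")

    @property
    def frames_per_participant(self) -> int:
        """1 primary frame per eye + frames_per_duction x 8 ductions x 2 eyes."""
        return 2 + 2 * 8 * self.frames_per_duction


@dataclass(frozen=True)
class GroundTruthRotation:
    """True rotation and artifacts behind one simulated frame."""

    participant_id: str
    eye: str
    gaze_label: str
    frame_index: int
    angle_deg: float
    direction_deg: Optional[float]
    axis: np.ndarray
    head_displacement_mm: np.ndarray


def reference_from_biometrics(
    model: BiometricModel, n_ring: int = 360
) -> ReferenceEllipse:
    """Ideal circular reference limbus implied by the biometric model."""
    r = model.limbus_radius_mm
    t = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
    emb = np.c_[
        r * np.cos(t), r * np.sin(t), np.full(n_ring, model.limbus_to_center_distance_mm)
    ]
    return ReferenceEllipse(
        center=np.zeros(2),
        semi_major_mm=r,
        semi_minor_mm=r,
        tilt_deg=0.0,
        embedding=emb,
        residual_rms_mm=0.0,
    )


def axis_for_direction(direction_deg: float) -> np.ndarray:
    """Listing's-plane axis moving gaze toward ``direction_deg``.

    A rotation about (-sin(phi), cos(phi), 0) displaces the projected
    ring center along (cos(phi), sin(phi)).
    """
    d = math.radians(direction_deg)
    return np.array([-math.sin(d), math.cos(d), 0.0])


def simulate_boundary(
    angle_deg: float,
    direction_deg: Optional[float],
    config: SimulationConfig,
    rng: np.random.Generator,
    participant_id: str = "sim",
    eye: str = "OD",
    gaze_label: str = PRIMARY,
    frame_index: int = 0,
) -> tuple[LimbusBoundary, GroundTruthRotation]:
    """Simulate one observed boundary from a ground-truth rotation.

    Builds the reference ring, rotates and projects it, then applies
    Gaussian point noise, removes a randomly placed occluded arc of at
    most the configured fraction, and adds a head translation (emitted
    in the ground truth so the correction step can undo it).
    """
    reference = reference_from_biometrics(config.biometrics, config.n_boundary_points)
    if angle_deg == 0.0 or direction_deg is None:
        ring = reference.ring2d.copy()
        axis = np.zeros(3)
        direction_deg = None
        angle_deg = 0.0
    else:
        axis = axis_for_direction(direction_deg)
        ring = project(rotate_points(reference.embedding, axis, angle_deg))

    if config.boundary_noise_sd > 0:
        ring = ring + rng.normal(0.0, config.boundary_noise_sd, ring.shape)
    if config.occlusion_fraction > 0:
        frac = float(rng.uniform(0.0, config.occlusion_fraction))
        n = ring.shape[0]
        n_drop = min(int(round(frac * n)), n - 5)
        if n_drop > 0:
            start = int(rng.integers(0, n))
            drop = (start + np.arange(n_drop)) % n
            keep = np.setdiff1d(np.arange(n), drop)
            ring = ring[keep]
    displacement = (
        rng.normal(0.0, config.head_translation_sd, 2)
        if config.head_translation_sd > 0
        else np.zeros(2)
    )
    ring = ring + displacement

    boundary = LimbusBoundary(
        points=ring,
        units="mm",
        participant_id=participant_id,
        eye=eye,
        gaze_label=gaze_label,
        frame_index=frame_index,
    )
    truth = GroundTruthRotation(
        participant_id=participant_id,
        eye=eye,
        gaze_label=gaze_label,
        frame_index=frame_index,
        angle_deg=float(angle_deg),
        direction_deg=direction_deg,
        axis=axis,
        head_displacement_mm=displacement,
    )
    return boundary, truth


def _subject_profiles(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    od = {
        label: max(config.duction_mean_profile[label] + rng.normal(0.0, config.between_subject_sd), 5.0)
        for label in GAZE_LABELS
    }
    os_ = {
        label: max(od[MIRROR_LABEL[label]] + rng.normal(0.0, config.interocular_asymmetry_sd), 5.0)
        for label in GAZE_LABELS
    }
    return {"OD": od, "OS": os_}


def simulate_participant_frames(
    config: SimulationConfig,
    participant_id: str,
    rng: np.random.Generator,
) -> tuple[list[LimbusBoundary], list[GroundTruthRotation]]:
    """All distilled frames for one participant.

    One primary-gaze frame per eye plus ``frames_per_duction`` frames
    per duction and eye: 82 frames with the default 5 fixations.
    """
    profiles = _subject_profiles(config, rng)
    boundaries: list[LimbusBoundary] = []
    truths: list[GroundTruthRotation] = []
    for eye in ("OD", "OS"):
        b, t = simulate_boundary(
            0.0, None, config, rng,
            participant_id=participant_id, eye=eye, gaze_label=PRIMARY, frame_index=0,
        )
        boundaries.append(b)
        truths.append(t)
        for label in GAZE_LABELS:
            for frame in range(config.frames_per_duction):
                mag = profiles[eye][label] + rng.normal(0.0, config.within_subject_sd)
                mag = float(np.clip(mag, 1.0, 89.0))
                direction = NOMINAL_DIRECTION_DEG[label] + rng.normal(
                    0.0, config.direction_jitter_sd
                )
                b, t = simulate_boundary(
                    mag, direction, config, rng,
                    participant_id=participant_id, eye=eye,
                    gaze_label=label, frame_index=frame,
                )
                boundaries.append(b)
                truths.append(t)
    return boundaries, truths


def simulate_boundaries_dataset(
    config: SimulationConfig,
) -> tuple[list[LimbusBoundary], list[GroundTruthRotation]]:
    """Frame-level dataset for the whole cohort (fixed config seed)."""
    rng = np.random.default_rng(config.seed)
    boundaries: list[LimbusBoundary] = []
    truths: list[GroundTruthRotation] = []
    for i in range(config.cohort_size):
        pid = f"P{i + 1:02d}"
        b, t = simulate_participant_frames(config, pid, rng)
        boundaries.extend(b)
        truths.extend(t)
    return boundaries, truths


@dataclass(frozen=True)
class ParticipantVectors:
    """Vector-level replicates for one participant."""

    participant_id: str
    profiles: dict[str, dict[str, float]]
    replicates: dict[tuple[str, str], tuple[DuctionVector, ...]]

    def duction_set(self, eye: str, replicate: int):
        from .indices import DuctionSet

        vectors = {
            label: self.replicates[(eye, label)][replicate] for label in GAZE_LABELS
        }
        return DuctionSet(self.participant_id, eye, vectors)

    def random_duction_set(self, eye: str, rng: np.random.Generator):
        """Draw one replicate per duction, as the resampling scheme does."""
        from .indices import DuctionSet

        vectors = {}
        for label in GAZE_LABELS:
            pool = self.replicates[(eye, label)]
            vectors[label] = pool[int(rng.integers(0, len(pool)))]
        return DuctionSet(self.participant_id, eye, vectors)

    def mean_duction_set(self, eye: str):
        from .indices import DuctionSet

        vectors = {}
        for label in GAZE_LABELS:
            pool = self.replicates[(eye, label)]
            mag = float(np.mean([v.magnitude_deg for v in pool]))
            # directions stay within a narrow arc of the nominal
            # meridian, so a linear mean of the jitter is adequate
            nominal = NOMINAL_DIRECTION_DEG[label]
            offs = [
                ((v.direction_deg - nominal + 180.0) % 360.0 - 180.0) for v in pool
            ]
            vectors[label] = DuctionVector(
                mag, nominal + float(np.mean(offs)), label=label, eye=eye
            )
        return DuctionSet(self.participant_id, eye, vectors)


@dataclass(frozen=True)
class CohortDataset:
    """Vector-level normative cohort with per-duction replicates."""

    config: SimulationConfig
    participants: tuple[ParticipantVectors, ...]

    def magnitude_pools(self, eye: str, label: str) -> dict[str, list[float]]:
        return {
            p.participant_id: [v.magnitude_deg for v in p.replicates[(eye, label)]]
            for p in self.participants
        }

    def direction_pools(self, eye: str, label: str) -> dict[str, list[float]]:
        return {
            p.participant_id: [v.direction_deg for v in p.replicates[(eye, label)]]
            for p in self.participants
        }

    def mean_duction_sets(self):
        return [
            (p.mean_duction_set("OD"), p.mean_duction_set("OS"))
            for p in self.participants
        ]


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Normative cohort of duction-vector replicates.

    Each participant gets a subject-level magnitude profile (cohort
    mean profile + between-subject noise, mirror-symmetric between the
    eyes up to the configured asymmetry), then ``frames_per_duction``
    replicates with within-subject magnitude noise and direction jitter
    about the nominal meridians. Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    participants = []
    for i in range(config.cohort_size):
        pid = f"P{i + 1:02d}"
        profiles = _subject_profiles(config, rng)
        replicates: dict[tuple[str, str], tuple[DuctionVector, ...]] = {}
        for eye in ("OD", "OS"):
            for label in GAZE_LABELS:
                vecs = []
                for _ in range(config.frames_per_duction):
                    mag = profiles[eye][label] + rng.normal(0.0, config.within_subject_sd)
                    mag = float(np.clip(mag, 1.0, 89.0))
                    direction = NOMINAL_DIRECTION_DEG[label] + rng.normal(
                        0.0, config.direction_jitter_sd
                    )
                    vecs.append(DuctionVector(mag, direction, label=label, eye=eye))
                replicates[(eye, label)] = tuple(vecs)
        participants.append(ParticipantVectors(pid, profiles, replicates))
    return CohortDataset(config=config, participants=tuple(participants))
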