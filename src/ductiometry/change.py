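"""Measurement-error statistics: SEm, MDC95, and resampled distributions.

The minimal detectable change at 95% confidence is
``MDC95 = 1.96 * SEm * sqrt(2)``, where the standard error of
measurement ``SEm = sqrt(MSE)`` comes from a repeated-measures ANOVA on
an N-participants x 2-occasions matrix. The default ANOVA is the
balanced two-way additive model (participant + occasion effects, no
replication), whose residual mean square has the closed form

    MSE = sum((x_ij - rowmean_i - colmean_j + grandmean)^2) / ((N-1)(k-1))

A participant-only (one-way) model is also offered; for k = 2 its MSE
reduces to ``sum(d_i^2) / (2N)`` with ``d_i`` the within-participant
difference.

Distributions of MDC values are produced by resampling: each iteration
draws two replicates per participant from their replicate pool, runs
the ANOVA, and records one MDC95.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .directions import wrap_signed

__all__ = [
    "MDC_FACTOR",
    "RepeatedMeasuresMatrix",
    "MDCResult",
    "ChangeFlag",
    "sem_from_rmanova",
    "mdc95",
    "resample_mdc",
    "resample_mdc_from_sampler",
    "flag_change",
]

#: MDC95 / SEm: 1.96 (z for 95% CI) times sqrt(2) for two measurements.
MDC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass(frozen=True)
class RepeatedMeasuresMatrix:
    """N participants x 2 repeated measurements of one metric."""

    values: np.ndarray
    metric_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("values must be an (N, 2) matrix")
        if v.shape[0] < 2:
            raise ValueError("at least 2 participants are required")
        if not np.all(np.isfinite(v)):
            raise ValueError("missing or non-finite cells are not allowed")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.shape[0])


def sem_from_rmanova(
    matrix: RepeatedMeasuresMatrix | np.ndarray, model: str = "two_way"
) -> float:
    """Standard error of measurement from a repeated-measures ANOVA.

    Parameters
    ----------
    matrix
        (N, 2) repeated-measures matrix.
    model
        ``"two_way"`` (participant + occasion additive effects, the
        default) or ``"one_way"`` (participant effect only).
    """
    if not isinstance(matrix, RepeatedMeasuresMatrix):
        matrix = RepeatedMeasuresMatrix(np.asarray(matrix, dtype=float))
    x = matrix.values
    n, k = x.shape
    if model == "two_way":
        resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
        sse = float(np.sum(resid**2))
        df = (n - 1) * (k - 1)
    elif model == "one_way":
        resid = x - x.mean(axis=1, keepdims=True)
        sse = float(np.sum(resid**2))
        df = n * (k - 1)
    else:
        raise ValueError("model must be 'two_way' or 'one_way'")
    return math.sqrt(max(sse, 0.0) / df)


def mdc95(sem: float) -> float:
    """Minimal detectable change at 95% confidence: 1.96 * SEm * sqrt(2)."""
    if sem < 0:
        raise ValueError("sem must be non-negative")
    return MDC_FACTOR * sem


@dataclass(frozen=True)
class MDCResult:
    """Resampled distribution of MDC95 values for one metric."""

    distribution: np.ndarray
    metric_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.distribution, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("distribution must be a non-empty 1D array")
        if np.any(d < 0):
            raise ValueError("MDC values must be non-negative")
        object.__setattr__(self, "distribution", d)

    @property
    def n_iterations(self) -> int:
        return int(self.distribution.size)

    @property
    def mean(self) -> float:
        return float(self.distribution.mean())

    @property
    def sem_distribution(self) -> np.ndarray:
        """The underlying SEm draws (MDC95 / (1.96 * sqrt(2)))."""
        return self.distribution / MDC_FACTOR

    @property
    def ci(self) -> tuple[float, float]:
        """Mean +/- 1.96 * SEM of the resampled distribution."""
        half = 1.96 * self.distribution.std(ddof=1) / math.sqrt(self.n_iterations) if self.n_iterations > 1 else 0.0
        return (self.mean - half, self.mean + half)

    def to_dict(self) -> dict:
        lo, hi = self.ci
        return {
            "metric": self.metric_name,
            "units": self.units,
            "n_iterations": self.n_iterations,
            "mean_mdc95": self.mean,
            "ci_low": lo,
            "ci_high": hi,
        }


def resample_mdc_from_sampler(
    sampler: Callable[[np.random.Generator], np.ndarray],
    n_iter: int = 1000,
    seed: Optional[int] = None,
    model: str = "two_way",
    metric_name: str = "",
    units: str = "",
) -> MDCResult:
    """Resampled MDC distribution driven by an arbitrary matrix sampler.

    ``sampler(rng)`` must return a fresh (N, 2) repeated-measures
    matrix; one MDC95 is recorded per iteration. A single seed drives
    all iterations, so results are reproducible.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.empty(n_iter)
    for i in range(n_iter):
        matrix = np.asarray(sampler(rng), dtype=float)
        draws[i] = mdc95(sem_from_rmanova(matrix, model=model))
    return MDCResult(draws, metric_name=metric_name, units=units)


def resample_mdc(
    pools: Mapping[str, Sequence[float]],
    n_iter: int = 1000,
    seed: Optional[int] = None,
    model: str = "two_way",
    metric_name: str = "",
    units: str = "",
) -> MDCResult:
    """Resampled MDC distribution from per-participant replicate pools.

    Each iteration builds an N x 2 matrix by drawing two replicates
    (without replacement) from every participant's pool, shuffling the
    combinations sampled across iterations. Participants with fewer
    than two replicates are excluded with a warning.
    """
    usable: dict[str, np.ndarray] = {}
    for pid in sorted(pools):
        vals = np.asarray(list(pools[pid]), dtype=float)
        if vals.size < 2:
            warnings.warn(
                f"participant {pid!r} has {vals.size} replicate(s); excluded",
                stacklevel=2,
            )
            continue
        usable[pid] = vals
    if len(usable) < 2:
        raise ValueError("need at least 2 participants with >= 2 replicates")
    ordered = [usable[pid] for pid in sorted(usable)]

    def sampler(rng: np.random.Generator) -> np.ndarray:
        return np.array(
            [vals[rng.choice(vals.size, size=2, replace=False)] for vals in ordered]
        )

    return resample_mdc_from_sampler(
        sampler, n_iter=n_iter, seed=seed, model=model,
        metric_name=metric_name, units=units,
    )


@dataclass(frozen=True)
class ChangeFlag:
    """Outcome of comparing a longitudinal change against an MDC."""

    delta: float
    threshold: float
    exceeds_mdc: bool


def flag_change(
    baseline: float,
    followup: float,
    mdc: MDCResult | float,
    circular: bool = False,
    units: Optional[str] = None,
) -> ChangeFlag:
    """Flag whether a follow-up value exceeds measurement error.

    The change is flagged when |followup - baseline| exceeds the mean
    resampled MDC95. For direction metrics pass ``circular=True`` so
    the difference is wrapped to the minimal arc in (-180, 180] first.
    """
    if isinstance(mdc, MDCResult):
        if units is not None and mdc.units and units != mdc.units:
            raise ValueError(
                f"unit mismatch: change in {units!r} vs MDC in {mdc.units!r}"
            )
        threshold = mdc.mean
    else:
        threshold = float(mdc)
    delta = followup - baseline
    if circular:
        delta = wrap_signed(delta)
    return ChangeFlag(delta=delta, threshold=threshold, exceeds_mdc=abs(delta) > threshold)
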