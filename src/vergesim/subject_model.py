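"""Parametric synthetic observer.

The observer responds to a horizontal vergence demand with a hard clamp at
its fusional amplitude: demands at or below the amplitude are met in full
(fusion), anything beyond leaves a residual demand that shows up, in its
entirety, as hitting deviation.  On top of the residual sits a baseline
aiming error modelled as a folded normal whose folded mean is calibrated to
the requested baseline bias (0.65 PD at defaults) with per-shot spread
``motor_noise_sd``.

An optional soft-saturation response is available for exploration
(``softness > 0`` turns the hard clamp into a smooth minimum); it is off by
default and unused by the standard protocol.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .geometry import WorldPoint, pd_to_lateral_offset

__all__ = [
    "SyntheticSubject",
    "CohortSpec",
    "achieved_vergence",
    "residual_demand",
    "simulate_hit",
    "sample_cohort",
    "folded_normal_location",
    "subject_seed_sequence",
]

CONVERGENCE = "convergence"
DIVERGENCE = "divergence"
_DIRECTIONS = (CONVERGENCE, DIVERGENCE, "none")


@dataclass(frozen=True)
class SyntheticSubject:
    """One synthetic orthotropic observer.

    ``pfv_amplitude`` / ``nfv_amplitude`` are the maximum sustainable
    convergence / divergence in PD.  ``baseline_bias_mean`` is the mean
    absolute aiming error (PD) with zero vergence demand;
    ``motor_noise_sd`` the per-shot spread of that error.
    """

    subject_id: str
    pfv_amplitude: float
    nfv_amplitude: float
    baseline_bias_mean: float = 0.65
    motor_noise_sd: float = 0.25
    wears_glasses: bool = False

    def __post_init__(self) -> None:
        for name in ("pfv_amplitude", "nfv_amplitude", "baseline_bias_mean", "motor_noise_sd"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    def amplitude_for(self, direction: str) -> float:
        if direction == CONVERGENCE:
            return self.pfv_amplitude
        if direction == DIVERGENCE:
            return self.nfv_amplitude
        raise ValueError(f"unknown vergence direction {direction!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling recipe for a synthetic cohort.

    Amplitudes are drawn from normal distributions truncated at zero.
    Default amplitude parameters sit inside the literature ranges for
    distance fusional reserves in young adults (PFV break 16-25 PD,
    NFV break roughly 5.6-9.7 PD).
    """

    n_subjects: int = 19
    pfv_amplitude_mean: float = 18.0
    pfv_amplitude_sd: float = 3.0
    nfv_amplitude_mean: float = 8.0
    nfv_amplitude_sd: float = 2.0
    baseline_bias_mean: float = 0.65
    motor_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("pfv_amplitude_sd", "nfv_amplitude_sd", "motor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_bias_mean < 0:
            raise ValueError("baseline_bias_mean must be >= 0")


def achieved_vergence(
    subject: SyntheticSubject,
    demand_pd: float,
    direction: str,
    softness: float = 0.0,
) -> float:
    """Vergence (PD) the subject actually performs for a given demand.

    Hard clamp by default: ``min(demand, amplitude)``.  With ``softness > 0``
    the clamp is replaced by the smooth minimum
    ``-s * log(exp(-demand/s) + exp(-amplitude/s))``.
    """
    if demand_pd < 0:
        raise ValueError(f"vergence demand must be >= 0, got {demand_pd!r}")
    if demand_pd == 0:
        return 0.0
    amplitude = subject.amplitude_for(direction)
    if softness <= 0:
        return min(demand_pd, amplitude)
    # smooth-min saturates below both demand and amplitude
    s = softness
    return max(0.0, -s * np.logaddexp(-demand_pd / s, -amplitude / s))


def residual_demand(
    subject: SyntheticSubject,
    demand_pd: float,
    direction: str,
    softness: float = 0.0,
) -> float:
    """Unmet part of the demand (PD); zero iff fusion succeeds."""
    return demand_pd - achieved_vergence(subject, demand_pd, direction, softness)


@lru_cache(maxsize=256)
def folded_normal_location(target_mean: float, sd: float) -> float:
    """Location ``mu >= 0`` such that ``E|N(mu, sd)| = target_mean``.

    The folded-normal mean is bounded below by ``sd * sqrt(2/pi)``; targets
    under that bound are unreachable and raise.  For ``sd = 0`` the
    location is the target itself.
    """
    if target_mean < 0 or sd < 0:
        raise ValueError("target_mean and sd must be >= 0")
    if sd == 0:
        return target_mean
    floor = sd * math.sqrt(2.0 / math.pi)
    if target_mean < floor - 1e-12:
        raise ValueError(
            f"folded mean {target_mean} unreachable with sd {sd} (minimum {floor:.4g})"
        )
    if target_mean <= floor:
        return 0.0

    def gap(mu: float) -> float:
        return stats.foldnorm.mean(mu / sd, scale=sd) - target_mean

    upper = target_mean + 10.0 * sd
    return optimize.brentq(gap, 0.0, upper, xtol=1e-12)


def _aiming_error_pd(subject: SyntheticSubject, rng: np.random.Generator) -> float:
    """One folded-normal aiming-error draw (PD, non-negative)."""
    mu = folded_normal_location(subject.baseline_bias_mean, subject.motor_noise_sd)
    if subject.motor_noise_sd == 0:
        return mu
    return abs(rng.normal(mu, subject.motor_noise_sd))


def simulate_hit(
    subject: SyntheticSubject,
    demand_pd: float,
    direction: str,
    balloon_center: WorldPoint,
    rng: np.random.Generator,
    sign: int = 1,
) -> WorldPoint:
    """Simulate one shot and return the hit point in the balloon plane.

    The horizontal miss magnitude is ``residual_demand + aiming error``
    (both in PD), converted back to metres at the balloon depth and applied
    with the given ``sign`` (+1 rightward).  Height is preserved.
    Deterministic given the generator state.
    """
    if not isinstance(rng, np.random.Generator):
        raise TypeError("rng must be a seeded numpy Generator")
    if sign not in (-1, 1):
        raise ValueError(f"sign must be +1 or -1, got {sign!r}")
    residual = residual_demand(subject, demand_pd, direction) if demand_pd > 0 else 0.0
    magnitude_pd = residual + _aiming_error_pd(subject, rng)
    dx = pd_to_lateral_offset(sign * magnitude_pd, balloon_center.z)
    return WorldPoint(balloon_center.x + dx, balloon_center.y, balloon_center.z)


def subject_seed_sequence(master_seed: int, subject_id: str) -> np.random.SeedSequence:
    """Stable per-subject seed stream derived from the master seed.

    Keyed on a hash of the subject id (not the cohort index), so adding or
    removing subjects never perturbs the draws of the others.
    """
    digest = hashlib.sha256(subject_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.SeedSequence([master_seed, key])


def sample_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> list[SyntheticSubject]:
    """Draw ``spec.n_subjects`` subjects with truncated-at-zero normal amplitudes."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    subjects = []
    for i in range(spec.n_subjects):
        pfv = _truncated_normal(rng, spec.pfv_amplitude_mean, spec.pfv_amplitude_sd)
        nfv = _truncated_normal(rng, spec.nfv_amplitude_mean, spec.nfv_amplitude_sd)
        subjects.append(
            SyntheticSubject(
                subject_id=f"s{i + 1:03d}",
                pfv_amplitude=pfv,
                nfv_amplitude=nfv,
                baseline_bias_mean=spec.baseline_bias_mean,
                motor_noise_sd=spec.motor_noise_sd,
            )
        )
    return subjects


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        if mean < 0:
            raise ValueError("degenerate amplitude draw with negative mean")
        return mean
    # rejection sampling; at the default parameters the reject rate is ~0
    for _ in range(10_000):
        draw = rng.normal(mean, sd)
        if draw >= 0:
            return float(draw)
    raise RuntimeError("truncated-normal sampling failed to produce a non-negative draw")
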