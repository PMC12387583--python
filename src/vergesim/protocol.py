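"""Session engine for the five-condition screening protocol.

A session runs CONTROL first, then the two divergence (NFV) conditions in
random order, then the two convergence (PFV) conditions in random order —
divergence always precedes convergence.  Each condition is a block of
``shots_per_condition`` shots; the balloon centre and the control eye are
re-drawn for every shot.

Randomness is split hierarchically: a master seed spawns one substream per
subject (keyed on the subject id), so cohort composition changes never
perturb the other subjects' records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import WorldConfig, WorldPoint, hitting_deviation_pd
from .subject_model import (
    CONVERGENCE,
    DIVERGENCE,
    SyntheticSubject,
    simulate_hit,
    subject_seed_sequence,
)

__all__ = [
    "Condition",
    "CONDITIONS",
    "ProtocolSpec",
    "ShotRecord",
    "condition_order",
    "sample_balloon_center",
    "run_session",
    "run_cohort",
    "records_to_frame",
    "write_shots_csv",
    "read_shots_csv",
    "SHOT_CSV_COLUMNS",
]


@dataclass(frozen=True)
class Condition:
    """One screening level: imposed camera rotation and required response."""

    label: str
    theta_cr_pd: float
    image_rotation: str  # none | inward | outward
    required_response: str  # none | divergence | convergence

    def __post_init__(self) -> None:
        if (self.theta_cr_pd == 0) != (self.image_rotation == "none"):
            raise ValueError("zero rotation iff no image rotation")
        pairing = {"none": "none", "inward": DIVERGENCE, "outward": CONVERGENCE}
        if pairing[self.image_rotation] != self.required_response:
            raise ValueError(
                f"rotation {self.image_rotation!r} requires response "
                f"{pairing[self.image_rotation]!r}, got {self.required_response!r}"
            )


CONDITIONS: dict[str, Condition] = {
    "CONTROL": Condition("CONTROL", 0.0, "none", "none"),
    "NFV10": Condition("NFV10", 10.0, "inward", DIVERGENCE),
    "NFV20": Condition("NFV20", 20.0, "inward", DIVERGENCE),
    "PFV10": Condition("PFV10", 10.0, "outward", CONVERGENCE),
    "PFV20": Condition("PFV20", 20.0, "outward", CONVERGENCE),
}


@dataclass(frozen=True)
class ProtocolSpec:
    shots_per_condition: int = 40
    condition_labels: tuple[str, ...] = ("CONTROL", "NFV10", "NFV20", "PFV10", "PFV20")
    randomize_within_blocks: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shots_per_condition < 1:
            raise ValueError("shots_per_condition must be >= 1")
        unknown = set(self.condition_labels) - CONDITIONS.keys()
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        if len(set(self.condition_labels)) != len(self.condition_labels):
            raise ValueError("condition labels must be unique")

    @property
    def conditions(self) -> list[Condition]:
        return [CONDITIONS[label] for label in self.condition_labels]


@dataclass(frozen=True)
class ShotRecord:
    subject_id: str
    condition: str
    shot_index: int
    control_eye: str  # left | right
    balloon_center: WorldPoint
    hit: WorldPoint
    deviation_pd: float


def condition_order(
    spec: ProtocolSpec, rng: np.random.Generator
) -> list[Condition]:
    """Block-randomized condition sequence.

    CONTROL (if present) always comes first; divergence conditions precede
    convergence conditions; order inside each block is shuffled.
    """
    conds = spec.conditions
    control = [c for c in conds if c.required_response == "none"]
    nfv = [c for c in conds if c.required_response == DIVERGENCE]
    pfv = [c for c in conds if c.required_response == CONVERGENCE]
    if spec.randomize_within_blocks:
        nfv = [nfv[i] for i in rng.permutation(len(nfv))]
        pfv = [pfv[i] for i in rng.permutation(len(pfv))]
    return control + nfv + pfv


def sample_balloon_center(world: WorldConfig, rng: np.random.Generator) -> WorldPoint:
    """Random balloon placement: offset magnitude uniform, then side uniform."""
    magnitude = world.lateral_offsets_m[rng.integers(len(world.lateral_offsets_m))]
    if magnitude == 0:
        x = 0.0
    else:
        side = world.offset_sides[rng.integers(len(world.offset_sides))]
        x = magnitude if side == "right" else -magnitude
    return WorldPoint(x, world.eye_height_m, world.viewing_distance_m)


def run_session(
    subject: SyntheticSubject,
    protocol: ProtocolSpec,
    world: WorldConfig,
    rng: np.random.Generator,
) -> list[ShotRecord]:
    """Run one subject through all conditions and return the shot records."""
    order = condition_order(protocol, rng)
    records: list[ShotRecord] = []
    for condition in order:
        for shot_index in range(1, protocol.shots_per_condition + 1):
            center = sample_balloon_center(world, rng)
            control_eye = "right" if rng.integers(2) else "left"
            # displacement side follows the control-eye assignment; scoring
            # uses absolute values so the convention is diagnostic only
            sign = 1 if control_eye == "right" else -1
            hit = simulate_hit(
                subject,
                condition.theta_cr_pd,
                condition.required_response,
                center,
                rng,
                sign=sign,
            )
            records.append(
                ShotRecord(
                    subject_id=subject.subject_id,
                    condition=condition.label,
                    shot_index=shot_index,
                    control_eye=control_eye,
                    balloon_center=center,
                    hit=hit,
                    deviation_pd=hitting_deviation_pd(hit, center),
                )
            )
    return records


def run_cohort(
    cohort: list[SyntheticSubject],
    protocol: ProtocolSpec,
    world: WorldConfig,
    master_seed: int,
) -> pd.DataFrame:
    """Run every subject and return the concatenated shot-record table.

    Subjects are processed in id order, each on its own RNG substream.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    ids = [s.subject_id for s in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in cohort")
    records: list[ShotRecord] = []
    for subject in sorted(cohort, key=lambda s: s.subject_id):
        rng = np.random.default_rng(subject_seed_sequence(master_seed, subject.subject_id))
        records.extend(run_session(subject, protocol, world, rng))
    return records_to_frame(records)


SHOT_CSV_COLUMNS = [
    "subject_id",
    "condition",
    "shot_index",
    "control_eye",
    "balloon_x_m",
    "balloon_y_m",
    "balloon_z_m",
    "hit_x_m",
    "hit_y_m",
    "hit_z_m",
    "deviation_pd",
]


def records_to_frame(records: list[ShotRecord]) -> pd.DataFrame:
    rows = [
        (
            r.subject_id,
            r.condition,
            r.shot_index,
            r.control_eye,
            r.balloon_center.x,
            r.balloon_center.y,
            r.balloon_center.z,
            r.hit.x,
            r.hit.y,
            r.hit.z,
            r.deviation_pd,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=SHOT_CSV_COLUMNS)


def write_shots_csv(frame: pd.DataFrame, path: str | Path) -> None:
    # default float formatting is shortest-roundtrip, so read_shots_csv
    # recovers coordinates and deviations bit-exactly
    frame.to_csv(path, index=False)


def read_shots_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(SHOT_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"shot CSV missing columns: {sorted(missing)}")
    return frame
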