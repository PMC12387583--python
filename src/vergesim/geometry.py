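"""Prism-diopter / visual-angle / world-coordinate conversions.

The prism diopter (PD) is defined by deflection: a ray deviated by angle
``theta`` is displaced ``100 * tan(theta)`` centimetres per metre of travel,
i.e. ``pd = 100 * tan(theta)``.  All conversions here are exact under that
definition — no small-angle approximation is used anywhere.

Hitting deviation is computed in the balloon plane (constant depth ``z``)
from the horizontal component only; the vertical coordinate is carried for
record-keeping but never scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "WorldConfig",
    "WorldPoint",
    "PrismAngle",
    "pd_to_degrees",
    "degrees_to_pd",
    "lateral_offset_to_pd",
    "pd_to_lateral_offset",
    "hitting_deviation_pd",
]

#: Depth tolerance (metres) when checking that a hit lies in the balloon plane.
DEPTH_TOLERANCE_M = 1e-6


@dataclass(frozen=True)
class WorldConfig:
    """Virtual scene geometry.

    Parameters
    ----------
    viewing_distance_m:
        Depth of the balloon plane in metres (default 6.0).
    balloon_diameter_m:
        Balloon diameter in metres (default 0.5).
    lateral_offsets_m:
        Offset magnitudes (metres) the balloon may be shifted from the
        central axis (default 0, 0.5 and 1.0 m).
    offset_sides:
        Sides a non-zero offset may fall on; sampled uniformly.
    eye_height_m:
        Height of the line of sight; the balloon centre is always placed
        at this height.
    """

    viewing_distance_m: float = 6.0
    balloon_diameter_m: float = 0.5
    lateral_offsets_m: tuple[float, ...] = (0.0, 0.5, 1.0)
    offset_sides: tuple[str, ...] = ("left", "right")
    eye_height_m: float = 1.5

    def __post_init__(self) -> None:
        if not self.viewing_distance_m > 0:
            raise ValueError("viewing_distance_m must be > 0")
        if not self.balloon_diameter_m > 0:
            raise ValueError("balloon_diameter_m must be > 0")
        if len(self.lateral_offsets_m) == 0:
            raise ValueError("lateral_offsets_m must be non-empty")
        if any(off < 0 for off in self.lateral_offsets_m):
            raise ValueError("lateral offsets must be >= 0")
        bad = set(self.offset_sides) - {"left", "right"}
        if bad:
            raise ValueError(f"invalid offset sides: {sorted(bad)}")


@dataclass(frozen=True)
class WorldPoint:
    """A point in world coordinates: x right (m), y up (m), z ahead (m)."""

    x: float
    y: float
    z: float


@dataclass(frozen=True)
class PrismAngle:
    """An angular deviation expressed in prism diopters.

    Positive magnitude means rightward displacement along the world
    horizontal axis.
    """

    magnitude_pd: float

    @property
    def degrees(self) -> float:
        return pd_to_degrees(self.magnitude_pd)

    @classmethod
    def from_degrees(cls, deg: float) -> "PrismAngle":
        return cls(degrees_to_pd(deg))


def pd_to_degrees(pd: float) -> float:
    """Convert prism diopters to degrees via the deflection definition.

    ``deg = atan(pd / 100)`` in degrees.  Odd and strictly increasing.
    """
    if not math.isfinite(pd):
        raise ValueError(f"prism-diopter value must be finite, got {pd!r}")
    return math.degrees(math.atan(pd / 100.0))


def degrees_to_pd(deg: float) -> float:
    """Convert degrees to prism diopters; inverse of :func:`pd_to_degrees`.

    Undefined for ``|deg| >= 90`` (the deflection diverges).
    """
    if not math.isfinite(deg):
        raise ValueError(f"degree value must be finite, got {deg!r}")
    if abs(deg) >= 90.0:
        raise ValueError(f"deflection undefined for |deg| >= 90, got {deg!r}")
    return 100.0 * math.tan(math.radians(deg))


def lateral_offset_to_pd(offset_m: float, distance_m: float) -> float:
    """Angular size in PD of a lateral offset viewed at a given distance.

    1 PD deflects a ray 1 cm laterally at 1 m, hence
    ``pd = 100 * offset / distance``.
    """
    if not distance_m > 0:
        raise ValueError(f"distance must be > 0, got {distance_m!r}")
    return 100.0 * offset_m / distance_m


def pd_to_lateral_offset(pd: float, distance_m: float) -> float:
    """Lateral displacement in metres produced by ``pd`` at ``distance_m``."""
    if not distance_m > 0:
        raise ValueError(f"distance must be > 0, got {distance_m!r}")
    return pd * distance_m / 100.0


def hitting_deviation_pd(hit: WorldPoint, balloon_center: WorldPoint) -> float:
    """Signed horizontal deviation of a hit from the balloon centre, in PD.

    Both points must lie in the same balloon plane (equal ``z`` within
    ``DEPTH_TOLERANCE_M``); only the horizontal component contributes.
    Positive means the hit is displaced rightward of the centre.
    """
    if abs(hit.z - balloon_center.z) > DEPTH_TOLERANCE_M:
        raise ValueError(
            "hit and balloon centre are not in the same depth plane: "
            f"{hit.z!r} vs {balloon_center.z!r}"
        )
    if not balloon_center.z > 0:
        raise ValueError(f"balloon plane depth must be > 0, got {balloon_center.z!r}")
    return 100.0 * (hit.x - balloon_center.x) / balloon_center.z
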