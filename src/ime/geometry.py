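"""Angular-error geometry for cursor-target acquisition tasks.

The task goal in a center-out BMI cursor task is *visible overlap* between a
cursor of radius ``R_C`` and a target of radius ``R_T``.  A velocity command
issued from a position a distance ``D`` from the target center therefore has
zero effective error whenever it points within the half-angle of the
cursor-target overlap zone,

    theta_Z = arcsin((R_C + R_T) / D),

and otherwise misses the overlap zone by ``theta_P = theta_C - theta_Z``,
where ``theta_C`` is the angle between the command and the target-center
direction.  ``theta_C`` (mode ``"center"``) ignores the geometry of the
overlap zone; ``theta_P`` (mode ``"overlap"``) encodes it.

All public functions accept and return degrees; radians are used internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorConfig",
    "InvalidGeometryError",
    "DegenerateDirectionError",
    "overlap_half_angle",
    "angular_error",
    "signed_angle",
]


class InvalidGeometryError(ValueError):
    """Raised for non-positive cursor-target distances."""


class DegenerateDirectionError(ValueError):
    """Raised when a direction vector has (near-)zero magnitude."""


@dataclass(frozen=True)
class ErrorConfig:
    """Geometry of the angular-error metric.

    Parameters
    ----------
    cursor_radius, target_radius
        Radii in mm; both must be positive.
    mode
        ``"overlap"`` applies the overlap-zone correction (theta_P);
        ``"center"`` measures the raw angle to the target center (theta_C)
        and ignores both radii.
    speed_threshold
        Optional lower bound (mm/s) below which velocity commands should be
        excluded from direction statistics; movement direction is noisy at
        low speeds.  Enforcement is left to callers via :meth:`admits_speed`.
    """

    cursor_radius: float = 7.0
    target_radius: float = 7.0
    mode: str = "overlap"
    speed_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.cursor_radius <= 0 or self.target_radius <= 0:
            raise InvalidGeometryError("cursor and target radii must be positive")
        if self.mode not in ("overlap", "center"):
            raise ValueError(f"mode must be 'overlap' or 'center', got {self.mode!r}")

    @property
    def contact_distance(self) -> float:
        """Center-to-center distance at which cursor and target overlap."""
        return self.cursor_radius + self.target_radius

    def admits_speed(self, speed) -> np.ndarray:
        """Boolean mask of speeds at or above the exclusion threshold."""
        return np.asarray(speed, dtype=float) >= self.speed_threshold

    def to_dict(self) -> dict:
        return {
            "cursor_radius": self.cursor_radius,
            "target_radius": self.target_radius,
            "mode": self.mode,
            "speed_threshold": self.speed_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorConfig":
        return cls(**d)


def overlap_half_angle(distance, config: ErrorConfig = ErrorConfig()):
    """Half-angle theta_Z (degrees) of the cursor-target overlap zone.

    ``theta_Z = arcsin((R_C + R_T) / D)`` for ``D > R_C + R_T``.  When the
    cursor already overlaps the target (``D <= R_C + R_T``) any near-target
    command succeeds and theta_Z is defined as 90 degrees, which keeps the
    function total.

    Accepts scalars or arrays; distances must be strictly positive.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d <= 0):
        raise InvalidGeometryError("cursor-target distance must be positive")
    ratio = np.minimum(config.contact_distance / d, 1.0)
    out = np.degrees(np.arcsin(ratio))
    return out.item() if np.isscalar(distance) else out


def angular_error(origin, direction, target_center, config: ErrorConfig = ErrorConfig()):
    """Unsigned angular error (degrees) of a velocity command.

    Parameters
    ----------
    origin : (..., 2) array
        Position(s) the command originates from, mm.
    direction : (..., 2) array
        Velocity command(s); must have nonzero magnitude.
    target_center : (2,) or (..., 2) array
        Target center position, mm.
    config
        Error geometry.  ``mode="center"`` returns theta_C in [0, 180];
        ``mode="overlap"`` returns theta_P = max(0, theta_C - theta_Z).
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    target_center = np.asarray(target_center, dtype=float)
    scalar = origin.ndim == 1

    to_target = target_center - origin
    dist = np.linalg.norm(to_target, axis=-1)
    if np.any(dist <= 0):
        raise InvalidGeometryError("origin coincides with target center")
    speed = np.linalg.norm(direction, axis=-1)
    if np.any(speed == 0):
        raise DegenerateDirectionError(
            "zero-magnitude velocity command; filter low-speed timesteps first"
        )

    cos = np.sum(direction * to_target, axis=-1) / (speed * dist)
    theta_c = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    if config.mode == "center":
        out = theta_c
    else:
        theta_z = np.degrees(np.arcsin(np.minimum(config.contact_distance / dist, 1.0)))
        out = np.maximum(0.0, theta_c - theta_z)
    return float(out) if scalar else out


def signed_angle(v1, v2):
    """Signed angle (degrees) from ``v1`` to ``v2``, CCW positive, in (-180, 180].

    Both vectors (or stacks of vectors along the last axis) must be nonzero.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if np.any(np.linalg.norm(v1, axis=-1) == 0) or np.any(np.linalg.norm(v2, axis=-1) == 0):
        raise DegenerateDirectionError("signed_angle requires nonzero vectors")
    cross = v1[..., 0] * v2[..., 1] - v1[..., 1] * v2[..., 0]
    dot = np.sum(v1 * v2, axis=-1)
    ang = np.degrees(np.arctan2(cross, dot))
    # atan2 returns [-180, 180]; map -180 to +180 so the range is (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return float(ang) if v1.ndim == 1 and v2.ndim == 1 else ang
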