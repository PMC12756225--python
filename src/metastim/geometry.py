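"""Slant/tilt surface-orientation algebra and cue-conflict construction.

A planar surface's 3D pose is parameterized by slant (rotation away from
the frontoparallel plane, degrees) and tilt (direction of the projection of
the surface normal onto the frontoparallel plane, degrees counter-clockwise
from screen-right).  The unit normal of a plane at slant ``s`` and tilt
``t`` is the standard spherical form::

    n(s, t) = (sin s cos t,  sin s sin t,  cos s)

so the frontoparallel plane (s = 0) has normal (0, 0, 1) and tilt is
undefined there.  All public interfaces take and return degrees; radians
are used internally only.

Cue-conflict stimuli pair a *texture* pose with a *disparity* pose built
symmetrically around a central orientation: the disparity cue takes the
central value minus half the discrepancy (so it is always the cue closer
to frontoparallel) and the texture cue takes the central value plus half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SLANT_EPSILON",
    "SurfaceOrientation",
    "CueConflictConfig",
    "normal_from_orientation",
    "orientation_from_normal",
    "expand_conflict",
    "angle_between",
]

#: Slant (degrees) below which tilt is reported as undefined.
SLANT_EPSILON = 0.1

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class SurfaceOrientation:
    """Pose of a plane: slant in [0, 90) and tilt in [0, 360), degrees.

    ``tilt_defined`` is False for (near-)frontoparallel poses, where tilt
    carries no information; the stored tilt is then a placeholder 0.
    """

    slant: float
    tilt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.slant < 90.0:
            raise ValueError(f"slant must be in [0, 90), got {self.slant}")
        object.__setattr__(self, "tilt", float(self.tilt) % 360.0)
        object.__setattr__(self, "slant", float(self.slant))

    @property
    def tilt_defined(self) -> bool:
        return self.slant >= SLANT_EPSILON


@dataclass(frozen=True)
class CueConflictConfig:
    """Central orientation plus slant/tilt discrepancies, degrees.

    Expanding the config yields a disparity pose at
    (sigma_c - delta_sigma/2, tau_c - delta_tau/2) and a texture pose at
    (sigma_c + delta_sigma/2, tau_c + delta_tau/2).
    """

    sigma_c: float
    tau_c: float
    delta_sigma: float = 0.0
    delta_tau: float = 0.0

    def expand(self) -> tuple[SurfaceOrientation, SurfaceOrientation]:
        return expand_conflict(self)


def normal_from_orientation(o: SurfaceOrientation | tuple[float, float]) -> np.ndarray:
    """Unit normal (3,) of the plane with the given slant/tilt pose.

    Also accepts a ``(slant, tilt)`` pair of scalars or of equal-shape
    arrays, in which case the result has shape ``(..., 3)``.
    """
    if isinstance(o, SurfaceOrientation):
        slant, tilt = o.slant, o.tilt
    else:
        slant, tilt = o
    slant = np.asarray(slant, dtype=float)
    tilt = np.asarray(tilt, dtype=float)
    if np.any(slant < 0.0) or np.any(slant >= 90.0):
        raise ValueError("slant must be in [0, 90) degrees")
    s = np.deg2rad(slant)
    t = np.deg2rad(tilt)
    n = np.stack(
        [np.sin(s) * np.cos(t), np.sin(s) * np.sin(t), np.cos(s)], axis=-1
    )
    return n


def orientation_from_normal(n: np.ndarray) -> SurfaceOrientation:
    """Invert :func:`normal_from_orientation` for a unit normal with z > 0."""
    n = np.asarray(n, dtype=float)
    if n.shape != (3,):
        raise ValueError("expected a single 3-vector")
    nrm = np.linalg.norm(n)
    if abs(nrm - 1.0) > 1e-6:
        raise ValueError(f"input is not unit norm: |n| = {nrm}")
    if n[2] <= 0.0:
        raise ValueError("normal must have z > 0 (slant in [0, 90))")
    slant = np.rad2deg(np.arccos(np.clip(n[2] / nrm, -1.0, 1.0)))
    if slant < SLANT_EPSILON:
        return SurfaceOrientation(slant=float(slant), tilt=0.0)
    tilt = np.rad2deg(np.arctan2(n[1], n[0])) % 360.0
    return SurfaceOrientation(slant=float(slant), tilt=float(tilt))


def expand_conflict(
    c: CueConflictConfig,
) -> tuple[SurfaceOrientation, SurfaceOrientation]:
    """Split a central pose into (disparity, texture) cue poses.

    The disparity cue takes -delta/2 on both parameters and the texture
    cue +delta/2, so the disparity cue is the one closer to frontoparallel
    for positive slant discrepancies.
    """
    sig_d = c.sigma_c - c.delta_sigma / 2.0
    sig_t = c.sigma_c + c.delta_sigma / 2.0
    if sig_d < 0.0:
        raise ValueError(
            f"disparity slant {sig_d} < 0; sigma_c must be >= delta_sigma/2"
        )
    if sig_t >= 90.0:
        raise ValueError(f"texture slant {sig_t} out of [0, 90)")
    disparity = SurfaceOrientation(sig_d, c.tau_c - c.delta_tau / 2.0)
    texture = SurfaceOrientation(sig_t, c.tau_c + c.delta_tau / 2.0)
    return disparity, texture


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two unit vectors, in [0, 180].

    Broadcasts over leading axes when given stacked ``(..., 3)`` inputs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dot = np.sum(a * b, axis=-1)
    cross = np.linalg.norm(np.cross(a, b), axis=-1)
    # atan2 form stays accurate near 0 and 180 deg, unlike arccos
    ang = np.rad2deg(np.arctan2(cross, dot))
    return float(ang) if ang.ndim == 0 else ang
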