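"""Cue-conflict stimulus construction as computable projective geometry.

The stimulus is a "metastimulus": a single apparent surface whose texture
gradient and binocular disparity specify different 3D poses.  It is built
in three steps:

1. a *texture plane* is textured with a jittered-grid Voronoi pattern and
   imaged by a cyclopic camera (midway between the eyes);
2. that cyclopic image is cast, projector-style, along the cyclopic rays
   onto an independently oriented *disparity plane* -- so the monocular
   (cyclopic) image is identical whatever the disparity plane's pose;
3. two cameras horizontally offset by half the interpupillary distance
   each render the back-projected surface, producing a stereo pair whose
   disparities are those of the disparity plane alone.

Coordinate frame: screen center at the origin, x to the viewer's right,
y up, z toward the viewer.  The cyclopic eye sits at (0, 0, VD); both cue
planes pass through the screen center.  Projections converge on the
screen plane (off-axis frusta), so points on the screen have zero
disparity and nearer points have positive (crossed) disparity, defined as
``left.x - right.x``.  All lengths are centimeters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .geometry import (
    CueConflictConfig,
    SurfaceOrientation,
    expand_conflict,
    normal_from_orientation,
)

__all__ = [
    "ViewingGeometry",
    "VoronoiTexture",
    "StereoPointPair",
    "generate_voronoi_sites",
    "plane_basis",
    "plane_point",
    "backproject",
    "cyclopic_project",
    "stereo_project",
    "disparity_field",
    "analytic_plane_disparity",
    "render_stereo_points",
    "save_anaglyph_png",
]


@dataclass(frozen=True)
class ViewingGeometry:
    """Observer/display geometry.

    viewing_distance : eye-to-screen distance, cm (default 50; the
        alternative 55 cm monitor distance is a plain override).
    ipd : interpupillary distance, cm; each eye sits ipd/2 off the
        cyclopic axis.
    aperture_diameter : circular aperture, degrees of visual angle.
    """

    viewing_distance: float = 50.0
    ipd: float = 6.4
    aperture_diameter: float = 35.5

    def __post_init__(self) -> None:
        if min(self.viewing_distance, self.ipd, self.aperture_diameter) <= 0:
            raise ValueError("all viewing-geometry fields must be positive")

    @property
    def aperture_radius_cm(self) -> float:
        half = np.deg2rad(self.aperture_diameter / 2.0)
        return float(self.viewing_distance * np.tan(half))

    def eye(self, which: str) -> np.ndarray:
        off = {"left": -self.ipd / 2.0, "right": self.ipd / 2.0, "cyclopic": 0.0}
        return np.array([off[which], 0.0, self.viewing_distance])

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ViewingGeometry":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class VoronoiTexture:
    """Jittered-grid Voronoi site set on the unit square."""

    grid_size: int
    jitter: float
    seed: int
    site_points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.site_points.shape != (self.grid_size**2, 2):
            raise ValueError("site count must equal grid_size**2")


@dataclass(frozen=True)
class StereoPointPair:
    left: np.ndarray   # (x, y) on screen, cm
    right: np.ndarray  # (x, y) on screen, cm

    @property
    def disparity(self) -> float:
        """Signed horizontal disparity, cm; positive = crossed (near)."""
        return float(self.left[0] - self.right[0])


def generate_voronoi_sites(
    grid_size: int, jitter: float, seed: int
) -> VoronoiTexture:
    """Regular grid of cell centers with per-axis uniform jitter.

    Sites live on the unit square; each of the ``grid_size**2`` cells
    contributes its center displaced by at most ``jitter/2`` cell widths
    per axis, so sites never leave their cell.  Deterministic for a
    fixed seed.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if not 0.0 <= jitter <= 1.0:
        raise ValueError("jitter must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cell = 1.0 / grid_size
    centers = (np.arange(grid_size) + 0.5) * cell
    gx, gy = np.meshgrid(centers, centers, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    sites = sites + rng.uniform(-jitter / 2.0, jitter / 2.0, sites.shape) * cell
    return VoronoiTexture(grid_size, jitter, seed, sites)


def plane_basis(pose: SurfaceOrientation) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal in-plane axes (e1, e2) and normal n for a pose.

    e1/e2 are the images of the screen x/y axes under the rotation that
    carries (0,0,1) to the plane normal about the axis z x n, so a
    frontoparallel pose gives the identity basis.
    """
    n = normal_from_orientation(pose)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, n)
    s = np.linalg.norm(v)
    if s < 1e-15:
        return np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]), n
    c = float(np.dot(z, n))
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx * ((1.0 - c) / s**2)
    return rot[:, 0].copy(), rot[:, 1].copy(), n


def plane_point(uv: np.ndarray, pose: SurfaceOrientation) -> np.ndarray:
    """3D point(s) for in-plane coordinates (cm) on a plane through origin."""
    uv = np.asarray(uv, dtype=float)
    e1, e2, _ = plane_basis(pose)
    return uv[..., 0, None] * e1 + uv[..., 1, None] * e2


def backproject(
    texture_point: np.ndarray,
    texture_pose: SurfaceOrientation,
    disparity_pose: SurfaceOrientation,
    vg: ViewingGeometry,
) -> np.ndarray:
    """Cast a texture-plane point along its cyclopic ray onto the
    disparity plane.

    ``texture_point`` is a 2D in-plane coordinate (cm) on the texture
    plane (or an (..., 2) stack).  The returned 3D point lies on both
    the cyclopic ray and the disparity plane, which is what makes the
    cyclopic image invariant to the disparity plane's pose.
    """
    p_t = plane_point(np.asarray(texture_point, dtype=float), texture_pose)
    n_d = normal_from_orientation(disparity_pose)
    eye = vg.eye("cyclopic")
    d = p_t - eye  # ray directions
    denom = d @ n_d
    num = -float(eye @ n_d)
    bad = np.abs(denom) < 1e-12
    if np.any(bad):
        raise ValueError("cyclopic ray parallel to the disparity plane")
    s = num / denom
    if np.any(s <= 0):
        raise ValueError("disparity plane is behind the eye along a ray")
    return eye + s[..., None] * d


def _project_through(p: np.ndarray, eye: np.ndarray) -> np.ndarray:
    """Intersect the eye->p line with the screen plane z = 0."""
    p = np.asarray(p, dtype=float)
    dz = eye[2] - p[..., 2]
    if np.any(p[..., 2] >= eye[2]):
        raise ValueError("point is not in front of the eye")
    s = eye[2] / dz
    return eye[:2] + s[..., None] * (p[..., :2] - eye[:2])


def cyclopic_project(p: np.ndarray, vg: ViewingGeometry) -> np.ndarray:
    """Screen image (x, y) of a 3D point seen from the cyclopic eye."""
    return _project_through(p, vg.eye("cyclopic"))


def stereo_project(p: np.ndarray, vg: ViewingGeometry) -> StereoPointPair:
    """Off-axis stereo projection of a 3D point onto the screen plane.

    Returns the left/right screen coordinates; both eyes share the y
    coordinate because the cameras are offset horizontally only.
    """
    left = _project_through(p, vg.eye("left"))
    right = _project_through(p, vg.eye("right"))
    return StereoPointPair(left=left, right=right)


def disparity_field(
    config: CueConflictConfig,
    vg: ViewingGeometry,
    sample_grid: np.ndarray,
) -> np.ndarray:
    """Signed horizontal disparity (cm) of the metastimulus at each
    texture-plane sample point.

    ``sample_grid`` is an (N, 2) array of in-plane coordinates on the
    texture plane.  Each point is back-projected onto the disparity
    plane and stereo-projected; by construction the result depends on
    the disparity pose only.
    """
    disparity_pose, texture_pose = expand_conflict(config)
    grid = np.atleast_2d(np.asarray(sample_grid, dtype=float))
    p3 = backproject(grid, texture_pose, disparity_pose, vg)
    left = _project_through(p3, vg.eye("left"))
    right = _project_through(p3, vg.eye("right"))
    return left[..., 0] - right[..., 0]


def analytic_plane_disparity(
    pose: SurfaceOrientation, vg: ViewingGeometry, sample_grid: np.ndarray
) -> np.ndarray:
    """Disparity of points lying directly on a single textured plane.

    Oracle for the zero-conflict case: the metastimulus pipeline must
    reduce to this when texture and disparity poses coincide.
    """
    grid = np.atleast_2d(np.asarray(sample_grid, dtype=float))
    p3 = plane_point(grid, pose)
    left = _project_through(p3, vg.eye("left"))
    right = _project_through(p3, vg.eye("right"))
    return left[..., 0] - right[..., 0]


def render_stereo_points(
    config: CueConflictConfig,
    vg: ViewingGeometry,
    texture: VoronoiTexture,
    extent_cm: float | None = None,
) -> dict[str, np.ndarray]:
    """Stereo screen coordinates of the texture's Voronoi sites.

    Sites on the unit square are scaled to ``[-extent, extent]`` cm on
    the texture plane (default: the aperture radius), back-projected and
    stereo-projected.  Returns ``{"left": (N,2), "right": (N,2)}``.
    """
    if extent_cm is None:
        extent_cm = vg.aperture_radius_cm
    disparity_pose, texture_pose = expand_conflict(config)
    uv = (texture.site_points - 0.5) * 2.0 * extent_cm
    p3 = backproject(uv, texture_pose, disparity_pose, vg)
    return {
        "left": _project_through(p3, vg.eye("left")),
        "right": _project_through(p3, vg.eye("right")),
    }


def save_anaglyph_png(
    path: str,
    config: CueConflictConfig,
    vg: ViewingGeometry,
    texture: VoronoiTexture,
    extent_cm: float | None = None,
) -> None:
    """Write a red/cyan anaglyph preview of the stimulus point set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    views = render_stereo_points(config, vg, texture, extent_cm)
    fig, ax = plt.subplots(figsize=(5, 5), facecolor="black")
    ax.scatter(*views["left"].T, s=6, c="red", alpha=0.8, linewidths=0)
    ax.scatter(*views["right"].T, s=6, c="cyan", alpha=0.8, linewidths=0)
    ax.set_facecolor("black")
    ax.set_aspect("equal")
    ax.set_xticks([]), ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
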