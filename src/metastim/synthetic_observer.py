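"""Synthetic observer: generative model of judgment-task responses.

No public human data exist for this paradigm, so every downstream stage
is exercised on a simulated observer whose responses have the structure
the analysis assumes:

* the mean perceived normal lies in the span of the two cue normals, at
  the point of the unit-norm ellipse selected by a generative disparity
  weight ``w_d``;
* ``w_d`` follows a linear model in log central slant (negative slope)
  and central tilt (positive gain), the qualitative pattern reported for
  human observers -- magnitudes are free parameters of the simulation
  and are not claims about any human dataset;
* responses are the mean normal corrupted by von Mises-Fisher noise on
  the sphere (the response-noise model is a construct of this package);
* an additive post-training shift on ``w_d`` is applied only for the
  designated adaptation group (joint-control training), emulating cue
  reweighting toward the texture cue for negative shifts;
* subjects differ by a Gaussian random intercept on ``w_d``.

Everything is deterministic under the study seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SurfaceOrientation, CueConflictConfig, normal_from_orientation
from .cue_weights import TOL_ANGLE_DEG

__all__ = [
    "WeightField",
    "ObserverNoise",
    "predicted_normal",
    "sample_perceived",
    "sample_vmf",
    "simulate_adjustment",
    "touch_stream_toward",
    "simulate_study",
]


@dataclass(frozen=True)
class WeightField:
    """Generative map from (sigma_c, tau_c) to the disparity weight.

    ``w_d = intercept + slope_logslant * ln(sigma_c) + tilt_gain * tau_c
    + interaction * tau_c * ln(sigma_c)``, with slant in degrees inside
    the log and tilt in degrees.  The default preset decreases in slant
    (slope_logslant < 0) and increases in tilt (tilt_gain > 0) and stays
    within (0, 1.5) over the tested 15-35 deg x 0-90 deg grid.

    ``post_shift`` is added to ``w_d`` in the post phase for subjects in
    ``adapt_group`` only; the negative default emulates reweighting
    toward the texture cue after joint-control training.
    ``subject_sd`` is the SD of the per-subject intercept offset.
    """

    intercept: float = 1.6
    slope_logslant: float = -0.25
    tilt_gain: float = 0.002
    interaction: float = 0.0
    post_shift: float = -0.25
    adapt_group: str = "ATD"
    subject_sd: float = 0.05

    def predict(
        self,
        sigma_c,
        tau_c,
        phase: str = "pre",
        group: str | None = None,
        subject_offset=0.0,
    ):
        """Generative w_d for central pose(s); broadcasts over arrays."""
        sigma_c = np.asarray(sigma_c, dtype=float)
        tau_c = np.asarray(tau_c, dtype=float)
        ls = np.log(sigma_c)
        w = (
            self.intercept
            + self.slope_logslant * ls
            + self.tilt_gain * tau_c
            + self.interaction * tau_c * ls
            + subject_offset
        )
        if phase == "post" and group == self.adapt_group:
            w = w + self.post_shift
        return w if w.ndim else float(w)


@dataclass
class ObserverNoise:
    """Directional response noise: von Mises-Fisher concentration kappa.

    ``kappa = inf`` gives a noiseless observer.  The generator is
    created once from ``seed`` and consumed across calls, so a study
    simulated with a fixed seed is reproducible draw by draw.
    """

    kappa: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        self.rng = np.random.default_rng(self.seed)


def _weights_on_ellipse(w_d, cue_dot):
    """w_t completing the pair (w_t, w_d) on the unit-norm ellipse.

    Takes the larger root of the ellipse quadratic in w_t, i.e. the
    branch on which w_d = 0 gives w_t = 1.
    """
    w_d = np.asarray(w_d, dtype=float)
    cue_dot = np.asarray(cue_dot, dtype=float)
    disc = 1.0 - w_d**2 * (1.0 - cue_dot**2)
    if np.any(disc < 0.0):
        raise ValueError(
            "requested w_d exceeds the ellipse bound 1/sqrt(1 - cue_dot^2); "
            "no admissible w_t exists"
        )
    return -cue_dot * w_d + np.sqrt(disc)


def predicted_normal(
    field: WeightField,
    config: CueConflictConfig,
    phase: str = "pre",
    group: str | None = None,
    subject_offset: float = 0.0,
) -> np.ndarray:
    """Mean perceived normal: the vector sum at the generative w_d.

    w_t is chosen so the weight pair lies on the unit-norm ellipse, so
    the returned vector is exactly unit norm.  For zero-conflict configs
    (parallel cues) the weights are unidentifiable and the common cue
    normal is returned directly.
    """
    disparity, texture = config.expand()
    n_d = normal_from_orientation(disparity)
    n_t = normal_from_orientation(texture)
    c = float(np.dot(n_t, n_d))
    if c >= np.cos(np.deg2rad(TOL_ANGLE_DEG)):
        return n_d
    w_d = field.predict(config.sigma_c, config.tau_c, phase, group, subject_offset)
    w_t = _weights_on_ellipse(w_d, c)
    return w_t * n_t + w_d * n_d


def sample_vmf(mean_dirs: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one von Mises-Fisher unit vector per row of ``mean_dirs``.

    Uses the exact inverse-CDF for the polar cosine in three dimensions,
    ``w = 1 + ln(u + (1 - u) e^(-2 kappa)) / kappa``, with a uniform
    azimuth in the tangent plane of each mean direction.
    """
    mu = np.atleast_2d(np.asarray(mean_dirs, dtype=float))
    n = mu.shape[0]
    if np.isinf(kappa):
        return mu.copy()
    u = rng.uniform(size=n)
    # log1p-stable form of ln(u + (1-u) e^{-2k}); exp(-2k) underflows
    # harmlessly to 0 for large kappa.
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    # tangent basis per mean direction
    helper = np.where(
        np.abs(mu[:, 2:3]) < 0.9, np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])
    )
    t1 = np.cross(mu, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(mu, t1)
    sin_theta = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    out = (
        w[:, None] * mu
        + (sin_theta * np.cos(phi))[:, None] * t1
        + (sin_theta * np.sin(phi))[:, None] * t2
    )
    return out


def sample_perceived(n_model: np.ndarray, noise: ObserverNoise) -> np.ndarray:
    """One noisy perceived normal around the model normal."""
    return sample_vmf(n_model, noise.kappa, noise.rng)[0]


def touch_stream_toward(
    target: SurfaceOrientation, n_frames: int, radius: float = 0.9
) -> np.ndarray:
    """Touchpad stream pressing toward the target's tilt direction."""
    t = np.deg2rad(target.tilt)
    return np.tile([radius * np.cos(t), radius * np.sin(t)], (n_frames, 1))


def simulate_adjustment(
    target: SurfaceOrientation,
    touch_stream: np.ndarray,
    start: SurfaceOrientation | None = None,
    step: float = 0.1,
    trigger_radius: float = 0.7,
    stop_tol: float = 0.05,
) -> list[SurfaceOrientation]:
    """Frame-by-frame touchpad adjustment dynamics.

    A touch at radial distance > ``trigger_radius`` from the pad center
    sets the adjustment direction to the touch angle atan2(y, x) and
    moves the surface pole ``step`` degrees per frame along it (so a
    touch opposite the current tilt walks the slant back down through
    zero); closer touches do nothing.  Slant is clamped to [0, 89.9]
    degrees.  The walk stops early once the pose is within ``stop_tol``
    degrees of the target pole.  Returns the pose after every frame.
    """
    touch_stream = np.atleast_2d(np.asarray(touch_stream, dtype=float))
    if np.any(np.abs(touch_stream) > 1.0):
        raise ValueError("touch coordinates must lie in [-1, 1]^2")
    pose = start or SurfaceOrientation(0.0, 0.0)
    v = pose.slant * np.array(
        [np.cos(np.deg2rad(pose.tilt)), np.sin(np.deg2rad(pose.tilt))]
    )
    tgt = target.slant * np.array(
        [np.cos(np.deg2rad(target.tilt)), np.sin(np.deg2rad(target.tilt))]
    )
    trajectory: list[SurfaceOrientation] = []
    for x, y in touch_stream:
        if np.hypot(x, y) > trigger_radius:
            theta = np.arctan2(y, x)
            v = v + step * np.array([np.cos(theta), np.sin(theta)])
            slant = min(float(np.hypot(*v)), 89.9)
            if slant < 1e-12:
                pose = SurfaceOrientation(0.0, 0.0)
            else:
                pose = SurfaceOrientation(
                    slant, float(np.rad2deg(np.arctan2(v[1], v[0]))) % 360.0
                )
        trajectory.append(pose)
        if np.hypot(*(v - tgt)) <= stop_tol:
            break
    return trajectory


def _normals_to_orientation_arrays(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.clip(n[:, 2], 1e-12, 1.0)
    slant = np.rad2deg(np.arccos(z / np.linalg.norm(n, axis=1)))
    slant = np.clip(slant, 0.0, np.nextafter(90.0, 0.0))
    tilt = np.rad2deg(np.arctan2(n[:, 1], n[:, 0])) % 360.0
    return slant, tilt


def simulate_study(
    design: pd.DataFrame,
    field: WeightField,
    noise: ObserverNoise,
    n_subjects: int = 10,
    group: str = "ATD",
    phases: tuple[str, ...] = ("pre", "post"),
) -> pd.DataFrame:
    """Simulate a pre/post study: one record per design row, subject and
    phase.

    Per-subject intercept offsets are drawn once from N(0, subject_sd)
    using the noise generator, so the whole study is reproducible from
    the noise seed.  Returns a trial table with perceived slant/tilt
    appended; subject ids are "S01", "S02", ...
    """
    base = design[
        ["sigma_c", "tau_c", "delta_sigma", "delta_tau", "repetition"]
    ].reset_index(drop=True)
    offsets = (
        noise.rng.normal(0.0, field.subject_sd, n_subjects)
        if field.subject_sd > 0
        else np.zeros(n_subjects)
    )
    frames = []
    for s in range(n_subjects):
        for phase in phases:
            df = base.copy()
            df.insert(0, "subject_id", f"S{s + 1:02d}")
            df.insert(1, "group", group)
            df.insert(2, "phase", phase)
            w_d = field.predict(
                df["sigma_c"].to_numpy(),
                df["tau_c"].to_numpy(),
                phase,
                group,
                offsets[s],
            )
            dis = normal_from_orientation(
                (
                    df["sigma_c"].to_numpy() - df["delta_sigma"].to_numpy() / 2,
                    df["tau_c"].to_numpy() - df["delta_tau"].to_numpy() / 2,
                )
            )
            tex = normal_from_orientation(
                (
                    df["sigma_c"].to_numpy() + df["delta_sigma"].to_numpy() / 2,
                    df["tau_c"].to_numpy() + df["delta_tau"].to_numpy() / 2,
                )
            )
            c = np.sum(dis * tex, axis=1)
            parallel = c >= np.cos(np.deg2rad(TOL_ANGLE_DEG))
            w_t = np.where(
                parallel, 0.0, _weights_on_ellipse(np.where(parallel, 0.0, w_d), np.where(parallel, 0.0, c))
            )
            w_d_eff = np.where(parallel, 1.0, w_d)
            n_model = w_t[:, None] * tex + w_d_eff[:, None] * dis
            perceived = sample_vmf(n_model, noise.kappa, noise.rng)
            slant, tilt = _normals_to_orientation_arrays(perceived)
            df["perceived_slant"] = slant
            df["perceived_tilt"] = tilt
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
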