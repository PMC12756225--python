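"""Texture/disparity cue-weight estimation from perceived surface normals.

The perceived normal of a two-cue surface is modeled as a weighted vector
sum of the two unit cue normals::

    n_p = w_t * n_t + w_d * n_d

Solving for the weights as an unconstrained 3x2 least-squares problem
(Moore-Penrose pseudo-inverse) does not force the combined vector to have
unit norm.  The constrained formulation imposes two scalar conditions,

    ||w_t n_t + w_d n_d||^2 - 1 = 0        (unit-norm constraint)
    n_p . (w_t n_t + w_d n_d) - 1 = 0      (percept-alignment constraint)

whose geometric reading in the (w_d, w_t) plane is a line (alignment)
meeting an ellipse (unit norm).  The ellipse is centered at the origin,
rotated by -pi/4, with semi-axes 1/sqrt(1 -+ n_t.n_d); the line's
coefficients are the dot products of the percept with each cue.  When the
percept lies in the plane spanned by the cues, the line is tangent to the
ellipse and the tangency point is the unique closed-form solution.  For
percepts off that plane no exact solution exists and the system is solved
in the least-squares sense by Levenberg-Marquardt.

Because both constraints are functions of the three pairwise dot products
only, every solver here works in that reduced scalar space; a vectorized
damped Gauss-Newton solver (:func:`estimate_batch`) handles whole trial
tables at once and agrees with the per-trial SciPy LM route to tight
tolerance.

Weights are never clipped: negative weights (percept outside the cue
wedge) are meaningful and must survive into pre/post comparisons.  When
the two cue normals are (near-)parallel the weights are unidentifiable --
any pair summing appropriately works -- and the symmetric pair (0.5, 0.5)
is reported with the ``degenerate`` flag set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TOL_SOLVE",
    "TOL_PLANE",
    "TOL_ANGLE_DEG",
    "WeightEstimate",
    "ConflictEllipse",
    "weights_pseudoinverse",
    "weights_closed_form",
    "weights_constrained",
    "conflict_ellipse",
    "line_ellipse_intersections",
    "estimate_batch",
]

#: Tolerance on the two constraint residuals for a converged estimate.
TOL_SOLVE = 1e-8
#: Tolerance on the scalar triple product det[n_t, n_d, n_p] for the
#: in-plane test used by the closed-form solver.
TOL_PLANE = 1e-9
#: Cue separation (degrees) below which the system is degenerate.
TOL_ANGLE_DEG = 0.5


@dataclass(frozen=True)
class WeightEstimate:
    """Result of one weight fit.

    ``residual_norm`` is the Euclidean norm of the 3-vector residual
    ``n_p - (w_t n_t + w_d n_d)`` for the pseudo-inverse method, and the
    norm of the two constraint residuals for the constrained methods.
    """

    w_t: float
    w_d: float
    residual_norm: float
    method: str  # "pseudoinverse" | "closed_form" | "levenberg_marquardt"
    degenerate: bool = False
    converged: bool = True


@dataclass(frozen=True)
class ConflictEllipse:
    """Unit-norm locus in the (w_d, w_t) plane for a given cue pair.

    The quadratic form w_t^2 + w_d^2 + 2 w_t w_d cue_dot = 1 is an
    ellipse centered at the origin and rotated by -pi/4; its semi-axes
    depend only on ``cue_dot = n_d . n_t``.  For cues less than 90 deg
    apart (cue_dot > 0) the major axis is the 1/sqrt(1 - cue_dot) one.
    """

    cue_dot: float
    rotation: float
    semi_axis_major: float
    semi_axis_minor: float

    def contains(self, w_t: float, w_d: float, tol: float = TOL_SOLVE) -> bool:
        q = w_t**2 + w_d**2 + 2.0 * w_t * w_d * self.cue_dot
        return bool(abs(q - 1.0) <= tol)


def conflict_ellipse(n_t: np.ndarray, n_d: np.ndarray) -> ConflictEllipse:
    """Ellipse of weight pairs giving a unit-norm combined vector."""
    c = float(np.dot(n_d, n_t))
    if abs(c) >= 1.0:
        raise ValueError("cue normals are parallel; the ellipse degenerates")
    return ConflictEllipse(
        cue_dot=c,
        rotation=-np.pi / 4.0,
        semi_axis_major=1.0 / np.sqrt(1.0 - c),
        semi_axis_minor=1.0 / np.sqrt(1.0 + c),
    )


def _dots(n_p: np.ndarray, n_t: np.ndarray, n_d: np.ndarray):
    a = float(np.dot(n_p, n_t))
    b = float(np.dot(n_p, n_d))
    c = float(np.dot(n_t, n_d))
    return a, b, c


def _is_parallel(c: float) -> bool:
    return abs(c) >= np.cos(np.deg2rad(TOL_ANGLE_DEG))


def _degenerate(method: str) -> WeightEstimate:
    # Any (w_t, w_d) with the right sum solves a zero-conflict system;
    # the symmetric pair keeps pipelines running and is flagged.
    return WeightEstimate(0.5, 0.5, 0.0, method, degenerate=True)


def _constraint_residuals(w_t, w_d, a, b, c):
    r1 = w_t**2 + w_d**2 + 2.0 * w_t * w_d * c - 1.0
    r2 = a * w_t + b * w_d - 1.0
    return r1, r2


def weights_pseudoinverse(
    n_p: np.ndarray, n_t: np.ndarray, n_d: np.ndarray
) -> WeightEstimate:
    """Unconstrained least-squares weights for the 3x2 system.

    Minimizes ``||n_p - (w_t n_t + w_d n_d)||``; the combined vector is
    not forced onto the unit sphere, so its norm is <= 1 for off-plane
    percepts.
    """
    a, b, c = _dots(n_p, n_t, n_d)
    if _is_parallel(c):
        return _degenerate("pseudoinverse")
    A = np.column_stack([n_t, n_d])
    w, *_ = np.linalg.lstsq(A, np.asarray(n_p, dtype=float))
    resid = float(np.linalg.norm(n_p - A @ w))
    return WeightEstimate(float(w[0]), float(w[1]), resid, "pseudoinverse")


def weights_closed_form(
    n_p: np.ndarray, n_t: np.ndarray, n_d: np.ndarray
) -> WeightEstimate:
    """Tangency solution for an in-plane percept.

    When ``n_p`` lies in span(n_t, n_d) (scalar triple product within
    :data:`TOL_PLANE`) the alignment line is tangent to the unit-norm
    ellipse and the tangency point solves the 2x2 Gram system
    ``[[1, c], [c, 1]] w = (n_p.n_t, n_p.n_d)``.  Off-plane percepts have
    no exact solution; a ValueError directs the caller to
    :func:`weights_constrained`.
    """
    a, b, c = _dots(n_p, n_t, n_d)
    if _is_parallel(c):
        return _degenerate("closed_form")
    triple = float(np.linalg.det(np.column_stack([n_t, n_d, n_p])))
    if abs(triple) > TOL_PLANE:
        raise ValueError(
            f"percept is off the cue plane (triple product {triple:.3e}); "
            "no exact line-ellipse intersection exists -- use "
            "weights_constrained"
        )
    det = 1.0 - c * c
    w_t = (a - c * b) / det
    w_d = (b - c * a) / det
    r1, r2 = _constraint_residuals(w_t, w_d, a, b, c)
    return WeightEstimate(
        w_t, w_d, float(np.hypot(r1, r2)), "closed_form"
    )


def _ellipse_init(a: float, b: float, c: float) -> tuple[float, float]:
    """Pseudo-inverse solution renormalized onto the ellipse (LM start)."""
    det = 1.0 - c * c
    w_t = (a - c * b) / det
    w_d = (b - c * a) / det
    q = w_t**2 + w_d**2 + 2.0 * w_t * w_d * c
    if q > 1e-12:
        s = 1.0 / np.sqrt(q)
        w_t, w_d = w_t * s, w_d * s
    else:
        w_t = w_d = 1.0 / np.sqrt(2.0 + 2.0 * c)
    return w_t, w_d


def weights_constrained(
    n_p: np.ndarray,
    n_t: np.ndarray,
    n_d: np.ndarray,
    init: tuple[float, float] | None = None,
    max_iter: int = 200,
) -> WeightEstimate:
    """Levenberg-Marquardt solution of the two-constraint system.

    Minimizes the sum of squares of the unit-norm and percept-alignment
    residuals.  For in-plane percepts both residuals vanish and the
    result matches :func:`weights_closed_form`; for off-plane percepts
    the best-compromise weights are returned with a positive
    ``residual_norm``.  Non-convergence is reported via the ``converged``
    flag on the best iterate, never as an exception.
    """
    a, b, c = _dots(n_p, n_t, n_d)
    if _is_parallel(c):
        return _degenerate("levenberg_marquardt")
    if init is None:
        init = _ellipse_init(a, b, c)

    def fun(w):
        return np.array(_constraint_residuals(w[0], w[1], a, b, c))

    def jac(w):
        w_t, w_d = w
        return np.array(
            [[2.0 * w_t + 2.0 * c * w_d, 2.0 * w_d + 2.0 * c * w_t], [a, b]]
        )

    sol = least_squares(
        fun, np.asarray(init, dtype=float), jac=jac, method="lm",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_iter,
    )
    r = fun(sol.x)
    resid = float(np.linalg.norm(r))
    # For an in-plane percept the residuals must vanish; off-plane they
    # cannot, so convergence is judged by the optimizer status instead.
    converged = bool(sol.status > 0)
    return WeightEstimate(
        float(sol.x[0]), float(sol.x[1]), resid, "levenberg_marquardt",
        converged=converged,
    )


def line_ellipse_intersections(
    cue_dot: float, line_t: float, line_d: float
) -> tuple[np.ndarray, float]:
    """Intersections of the alignment line with the unit-norm ellipse.

    The line is ``line_t * w_t + line_d * w_d = 1`` with coefficients
    ``line_t = n_p.n_t`` and ``line_d = n_p.n_d``.  Returns the
    intersection points as an array of (w_t, w_d) rows (empty if the
    line misses the ellipse) together with the discriminant of the
    substituted quadratic: zero at tangency, negative for a miss.

    This is a diagnostic/oracle routine: the closed-form solver obtains
    the tangency point directly from the Gram system.
    """
    c = float(cue_dot)
    a, b = float(line_t), float(line_d)
    if abs(a) < 1e-15 and abs(b) < 1e-15:
        raise ValueError("degenerate line: both coefficients are zero")
    # Substitute the better-conditioned variable.
    swap = abs(b) > abs(a)
    if swap:
        a, b = b, a
    # w_t = (1 - b w_d)/a into the ellipse quadratic -> A w_d^2 + B w_d + C.
    A = b * b / (a * a) + 1.0 - 2.0 * c * b / a
    B = -2.0 * b / (a * a) + 2.0 * c / a
    C = 1.0 / (a * a) - 1.0
    disc = B * B - 4.0 * A * C
    if disc < 0.0:
        return np.empty((0, 2)), float(disc)
    roots = np.array([(-B - np.sqrt(max(disc, 0.0))) / (2.0 * A),
                      (-B + np.sqrt(max(disc, 0.0))) / (2.0 * A)])
    other = (1.0 - b * roots) / a
    pts = np.column_stack([other, roots])  # (w_t, w_d) before any swap
    if swap:
        pts = pts[:, ::-1]
    return pts, float(disc)


def estimate_batch(
    n_p: np.ndarray,
    n_t: np.ndarray,
    n_d: np.ndarray,
    max_iter: int = 80,
) -> dict[str, np.ndarray]:
    """Vectorized constrained weight estimation for stacked trials.

    Parameters are ``(N, 3)`` arrays of perceived, texture and disparity
    unit normals.  Runs a damped Gauss-Newton (Levenberg-Marquardt)
    iteration on the reduced two-residual system for all rows at once.
    Returns arrays ``w_t``, ``w_d``, ``residual_norm``, ``degenerate``
    and ``converged``.  Degenerate (near-parallel cue) rows are assigned
    the symmetric (0.5, 0.5) pair and excluded from iteration.
    """
    n_p = np.atleast_2d(np.asarray(n_p, dtype=float))
    n_t = np.atleast_2d(np.asarray(n_t, dtype=float))
    n_d = np.atleast_2d(np.asarray(n_d, dtype=float))
    a = np.sum(n_p * n_t, axis=1)
    b = np.sum(n_p * n_d, axis=1)
    c = np.sum(n_t * n_d, axis=1)
    n = a.size

    degenerate = np.abs(c) >= np.cos(np.deg2rad(TOL_ANGLE_DEG))
    ok = ~degenerate
    w_t = np.full(n, 0.5)
    w_d = np.full(n, 0.5)

    # init: pseudo-inverse solution renormalized onto the ellipse
    det = np.where(ok, 1.0 - c * c, 1.0)
    wt = (a - c * b) / det
    wd = (b - c * a) / det
    q = wt**2 + wd**2 + 2.0 * wt * wd * c
    safe = q > 1e-12
    scale = np.where(safe, 1.0 / np.sqrt(np.where(safe, q, 1.0)), 1.0)
    wt = np.where(safe, wt * scale, 1.0 / np.sqrt(2.0 + 2.0 * np.clip(c, -0.999, None)))
    wd = np.where(safe, wd * scale, wt)

    lam = np.full(n, 1e-3)

    def residuals(wt, wd):
        r1 = wt**2 + wd**2 + 2.0 * wt * wd * c - 1.0
        r2 = a * wt + b * wd - 1.0
        return r1, r2

    r1, r2 = residuals(wt, wd)
    cost = r1**2 + r2**2
    for _ in range(max_iter):
        j11 = 2.0 * wt + 2.0 * c * wd
        j12 = 2.0 * wd + 2.0 * c * wt
        # J^T J (2x2, symmetric) and J^T r
        h11 = j11 * j11 + a * a
        h12 = j11 * j12 + a * b
        h22 = j12 * j12 + b * b
        g1 = j11 * r1 + a * r2
        g2 = j12 * r1 + b * r2
        d11 = h11 * (1.0 + lam)
        d22 = h22 * (1.0 + lam)
        den = d11 * d22 - h12 * h12
        den = np.where(np.abs(den) < 1e-300, 1e-300, den)
        s1 = -(d22 * g1 - h12 * g2) / den
        s2 = -(d11 * g2 - h12 * g1) / den
        wt_new = wt + s1
        wd_new = wd + s2
        r1_new, r2_new = residuals(wt_new, wd_new)
        cost_new = r1_new**2 + r2_new**2
        improve = (cost_new < cost) & ok
        wt = np.where(improve, wt_new, wt)
        wd = np.where(improve, wd_new, wd)
        r1 = np.where(improve, r1_new, r1)
        r2 = np.where(improve, r2_new, r2)
        cost = np.where(improve, cost_new, cost)
        lam = np.where(improve, lam / 3.0, lam * 10.0)
        lam = np.clip(lam, 1e-12, 1e12)
        grad_inf = np.maximum(np.abs(g1), np.abs(g2))
        if np.all(grad_inf[ok] < 1e-12):
            break

    grad_inf = np.maximum(np.abs(j11 * r1 + a * r2), np.abs(j12 * r1 + b * r2))
    converged = ok & (grad_inf < 1e-8)
    w_t = np.where(ok, wt, w_t)
    w_d = np.where(ok, wd, w_d)
    resid = np.where(ok, np.sqrt(cost), 0.0)
    return {
        "w_t": w_t,
        "w_d": w_d,
        "residual_norm": resid,
        "degenerate": degenerate,
        "converged": converged | degenerate,
    }
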