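"""Constrained vector-sum weight estimation: solvers, ellipse, oracles."""

import numpy as np
import pytest

from metastim import (
    SurfaceOrientation,
    conflict_ellipse,
    normal_from_orientation,
    weights_closed_form,
    weights_constrained,
    weights_pseudoinverse,
    estimate_batch,
)
from metastim.cue_weights import line_ellipse_intersections, TOL_SOLVE

from conftest import random_cue_pair, random_inplane_percept


def cues_30_apart():
    n_t = normal_from_orientation(SurfaceOrientation(40.0, 0.0))
    n_d = normal_from_orientation(SurfaceOrientation(10.0, 0.0))
    return n_t, n_d


def combined(w, n_t, n_d):
    return w.w_t * n_t + w.w_d * n_d


class TestPseudoinverse:
    def test_percept_equal_to_texture_cue(self):
        n_t, n_d = cues_30_apart()
        est = weights_pseudoinverse(n_t, n_t, n_d)
        assert est.w_t == pytest.approx(1.0, abs=1e-12)
        assert est.w_d == pytest.approx(0.0, abs=1e-12)
        assert est.residual_norm == pytest.approx(0.0, abs=1e-12)

    def test_inplane_percept_attains_zero_residual(self, rng):
        n_t, n_d = random_cue_pair(rng)
        n_p = random_inplane_percept(rng, n_t, n_d)
        est = weights_pseudoinverse(n_p, n_t, n_d)
        assert est.residual_norm < 1e-10
        assert np.linalg.norm(combined(est, n_t, n_d)) == pytest.approx(1.0, abs=1e-10)

    def test_offplane_percept_shrinks_combined_norm(self, rng):
        """Least squares projects the percept onto the cue plane, so the
        combined vector is shorter than the unit percept."""
        for _ in range(20):
            n_t, n_d = random_cue_pair(rng)
            n_p = normal_from_orientation(
                SurfaceOrientation(rng.uniform(1, 60), rng.uniform(0, 360))
            )
            est = weights_pseudoinverse(n_p, n_t, n_d)
            v = combined(est, n_t, n_d)
            assert est.residual_norm == pytest.approx(
                np.linalg.norm(n_p - v), abs=1e-12
            )
            assert np.linalg.norm(v) <= 1.0 + 1e-12


class TestConflictEllipse:
    def test_orthogonal_cues_give_unit_circle(self):
        n_t = np.array([1.0, 0.0, 0.0])
        n_d = np.array([0.0, 0.0, 1.0])
        e = conflict_ellipse(n_t, n_d)
        assert e.semi_axis_major == pytest.approx(1.0)
        assert e.semi_axis_minor == pytest.approx(1.0)

    def test_rotation_is_minus_quarter_pi(self, rng):
        for _ in range(10):
            e = conflict_ellipse(*random_cue_pair(rng))
            assert e.rotation == -np.pi / 4.0

    def test_axes_match_quadratic_form_eigendecomposition(self):
        """Oracle: semi-axes are reciprocal square roots of the
        eigenvalues of the quadratic form [[1, c], [c, 1]]."""
        n_t, n_d = cues_30_apart()
        c = float(n_t @ n_d)
        assert c == pytest.approx(np.cos(np.deg2rad(30.0)), abs=1e-12)
        e = conflict_ellipse(n_t, n_d)
        evals = np.linalg.eigvalsh(np.array([[1.0, c], [c, 1.0]]))
        np.testing.assert_allclose(
            sorted([e.semi_axis_major, e.semi_axis_minor]),
            sorted(1.0 / np.sqrt(evals)),
            rtol=1e-12,
        )
        assert e.semi_axis_major >= e.semi_axis_minor

    def test_parallel_cues_rejected(self):
        n = np.array([0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            conflict_ellipse(n, n)


class TestClosedForm:
    def test_percept_equal_to_disparity_cue(self):
        n_t, n_d = cues_30_apart()
        est = weights_closed_form(n_d, n_t, n_d)
        assert est.w_t == pytest.approx(0.0, abs=1e-10)
        assert est.w_d == pytest.approx(1.0, abs=1e-10)

    def test_bisector_weights_match_brute_force(self):
        """Symmetric percept between cues 30 deg apart: the tangency pair
        is w = 1/(2 cos 15), cross-checked by a dense grid search on the
        two-constraint objective."""
        n_t, n_d = cues_30_apart()
        n_p = n_t + n_d
        n_p = n_p / np.linalg.norm(n_p)
        est = weights_closed_form(n_p, n_t, n_d)
        expected = 1.0 / (2.0 * np.cos(np.deg2rad(15.0)))
        assert est.w_t == pytest.approx(expected, abs=1e-10)
        assert est.w_d == pytest.approx(expected, abs=1e-10)
        # brute-force oracle on the constraint pair
        grid = np.linspace(0.3, 0.8, 2001)
        wt, wd = np.meshgrid(grid, grid)
        c = float(n_t @ n_d)
        a, b = float(n_p @ n_t), float(n_p @ n_d)
        obj = (wt**2 + wd**2 + 2 * wt * wd * c - 1) ** 2 + (a * wt + b * wd - 1) ** 2
        i = np.unravel_index(np.argmin(obj), obj.shape)
        # the objective valley is quartically flat along the constraint
        # line, so the grid localizes the minimum only coarsely; the
        # closed form must lie in that valley and do at least as well
        assert wt[i] == pytest.approx(expected, abs=0.05)
        assert wd[i] == pytest.approx(expected, abs=0.05)
        obj_cf = (
            est.w_t**2 + est.w_d**2 + 2 * est.w_t * est.w_d * c - 1
        ) ** 2 + (a * est.w_t + b * est.w_d - 1) ** 2
        assert obj_cf <= obj[i] + 1e-15

    def test_no_conflict_reports_degenerate_symmetric_pair(self):
        n = normal_from_orientation(SurfaceOrientation(20.0, 30.0))
        est = weights_closed_form(n, n, n)
        assert est.degenerate
        assert (est.w_t, est.w_d) == (0.5, 0.5)

    def test_offplane_percept_raises(self, rng):
        n_t, n_d = cues_30_apart()
        n_p = normal_from_orientation(SurfaceOrientation(25.0, 40.0))
        with pytest.raises(ValueError, match="weights_constrained"):
            weights_closed_form(n_p, n_t, n_d)

    def test_tangency_discriminant_zero_inplane(self, rng):
        """For in-plane percepts the alignment line is tangent to the
        ellipse: the substituted quadratic has zero discriminant."""
        for _ in range(50):
            n_t, n_d = random_cue_pair(rng)
            n_p = random_inplane_percept(rng, n_t, n_d)
            pts, disc = line_ellipse_intersections(
                float(n_t @ n_d), float(n_p @ n_t), float(n_p @ n_d)
            )
            assert abs(disc) <= 1e-8
            if len(pts):
                est = weights_closed_form(n_p, n_t, n_d)
                np.testing.assert_allclose(
                    pts.mean(axis=0), [est.w_t, est.w_d], atol=1e-6
                )


class TestConstrained:
    def test_matches_closed_form_inplane(self, rng):
        for _ in range(50):
            n_t, n_d = random_cue_pair(rng)
            n_p = random_inplane_percept(rng, n_t, n_d)
            cf = weights_closed_form(n_p, n_t, n_d)
            lm = weights_constrained(n_p, n_t, n_d)
            # at the tangency the Jacobian is singular, so parameter
            # accuracy is limited to ~sqrt(eps); 1e-7 is the float64 floor
            assert lm.w_t == pytest.approx(cf.w_t, abs=1e-7)
            assert lm.w_d == pytest.approx(cf.w_d, abs=1e-7)
            assert lm.residual_norm < TOL_SOLVE

    def test_offplane_matches_grid_minimization_oracle(self):
        """Percept nudged 2 deg off the cue plane: LM minimizes the
        two-constraint sum of squares; a dense grid search agrees."""
        n_t, n_d = cues_30_apart()
        bis = (n_t + n_d) / np.linalg.norm(n_t + n_d)
        axis = np.cross(n_t, n_d)
        axis /= np.linalg.norm(axis)
        ang = np.deg2rad(2.0)
        n_p = np.cos(ang) * bis + np.sin(ang) * axis
        est = weights_constrained(n_p, n_t, n_d)
        assert est.residual_norm > 1e-4
        c, a, b = float(n_t @ n_d), float(n_p @ n_t), float(n_p @ n_d)
        grid = np.linspace(est.w_t - 0.05, est.w_t + 0.05, 801)
        wt, wd = np.meshgrid(grid, grid + (est.w_d - est.w_t))
        obj = (wt**2 + wd**2 + 2 * wt * wd * c - 1) ** 2 + (a * wt + b * wd - 1) ** 2
        i = np.unravel_index(np.argmin(obj), obj.shape)
        assert wt[i] == pytest.approx(est.w_t, abs=2e-4)
        assert wd[i] == pytest.approx(est.w_d, abs=2e-4)

    def test_solution_continuous_in_perturbation(self):
        n_t, n_d = cues_30_apart()
        bis = (n_t + n_d) / np.linalg.norm(n_t + n_d)
        axis = np.cross(n_t, n_d)
        axis /= np.linalg.norm(axis)
        prev = None
        for deg in (0.0, 0.5, 1.0, 1.5, 2.0):
            ang = np.deg2rad(deg)
            n_p = np.cos(ang) * bis + np.sin(ang) * axis
            est = weights_constrained(n_p, n_t, n_d)
            if prev is not None:
                assert abs(est.w_t - prev.w_t) < 0.02
                assert abs(est.w_d - prev.w_d) < 0.02
            prev = est

    def test_init_independence_inplane(self, rng):
        for _ in range(20):
            n_t, n_d = random_cue_pair(rng)
            n_p = random_inplane_percept(rng, n_t, n_d)
            a = weights_constrained(n_p, n_t, n_d)
            b = weights_constrained(n_p, n_t, n_d, init=(0.5, 0.5))
            assert a.w_t == pytest.approx(b.w_t, abs=1e-6)
            assert a.w_d == pytest.approx(b.w_d, abs=1e-6)

    def test_parallel_cues_flagged(self):
        n = normal_from_orientation(SurfaceOrientation(20.0, 0.0))
        est = weights_constrained(n, n, n)
        assert est.degenerate and (est.w_t, est.w_d) == (0.5, 0.5)


class TestProperties:
    def test_three_way_solver_agreement_inplane(self, rng):
        """Pseudo-inverse, closed form and LM agree pairwise for percepts
        in the cue plane, and the constrained ones satisfy both
        constraints."""
        for _ in range(200):
            n_t, n_d = random_cue_pair(rng)
            n_p = random_inplane_percept(rng, n_t, n_d)
            pi = weights_pseudoinverse(n_p, n_t, n_d)
            cf = weights_closed_form(n_p, n_t, n_d)
            lm = weights_constrained(n_p, n_t, n_d)
            for x, y in ((pi, cf), (cf, lm), (pi, lm)):
                assert abs(x.w_t - y.w_t) < 1e-6
                assert abs(x.w_d - y.w_d) < 1e-6
            v = combined(lm, n_t, n_d)
            assert abs(np.linalg.norm(v) ** 2 - 1.0) < 1e-8
            assert abs(float(n_p @ v) - 1.0) < 1e-8

    def test_recovery_of_generative_weights(self, rng):
        """Percepts built from weight pairs on the ellipse are recovered
        by all three solvers."""
        for _ in range(100):
            n_t, n_d = random_cue_pair(rng)
            c = float(n_t @ n_d)
            w_d = rng.uniform(-0.2, 1.0 / np.sqrt(1 - c * c) * 0.95)
            w_t = -c * w_d + np.sqrt(1.0 - w_d**2 * (1 - c * c))
            n_p = w_t * n_t + w_d * n_d
            for est in (
                weights_pseudoinverse(n_p, n_t, n_d),
                weights_closed_form(n_p, n_t, n_d),
                weights_constrained(n_p, n_t, n_d),
            ):
                assert est.w_t == pytest.approx(w_t, abs=1e-6)
                assert est.w_d == pytest.approx(w_d, abs=1e-6)

    def test_weight_sum_at_least_one_for_nonnegative_pairs(self, rng):
        """On the unit-norm ellipse with cue_dot < 1, non-negative weight
        pairs satisfy w_t + w_d >= 1, with equality only as the conflict
        vanishes."""
        for _ in range(200):
            n_t, n_d = random_cue_pair(rng)
            n_p = random_inplane_percept(rng, n_t, n_d)
            est = weights_constrained(n_p, n_t, n_d)
            if est.degenerate or est.w_t < 0 or est.w_d < 0:
                continue
            assert est.w_t + est.w_d >= 1.0 - 1e-9
            if min(est.w_t, est.w_d) > 1e-3:
                assert est.w_t + est.w_d > 1.0

    def test_batch_agrees_with_scipy_lm(self, rng):
        n_ts, n_ds, n_ps = [], [], []
        for _ in range(100):
            n_t, n_d = random_cue_pair(rng)
            s = rng.uniform(1, 60)
            t = rng.uniform(0, 360)
            n_ps.append(normal_from_orientation(SurfaceOrientation(s, t)))
            n_ts.append(n_t)
            n_ds.append(n_d)
        batch = estimate_batch(np.array(n_ps), np.array(n_ts), np.array(n_ds))
        for i in range(100):
            ref = weights_constrained(n_ps[i], n_ts[i], n_ds[i])
            assert batch["w_t"][i] == pytest.approx(ref.w_t, rel=1e-6, abs=1e-6)
            assert batch["w_d"][i] == pytest.approx(ref.w_d, rel=1e-6, abs=1e-6)
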