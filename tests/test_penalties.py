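"""SCAD primitives and the group-penalized solvers against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from rocselect.data import apply_weights, build_stacked_design, center_two_group
from rocselect.penalties import (
    PenaltySpec,
    fit_group_scad,
    fit_separate_scad,
    group_lasso_path,
    group_scad_path,
    penalized_objective,
    scad_derivative,
    scad_penalty,
    separate_scad_path,
)

from conftest import random_sample
from oracles import brute_force_group_scad


class TestScadPrimitives:
    def test_derivative_piecewise_values(self):
        lam, a = 0.8, 3.7
        assert scad_derivative(0.5 * lam, lam, a) == pytest.approx(lam)
        assert scad_derivative(a * lam, lam, a) == pytest.approx(0.0)
        assert scad_derivative(2 * lam, lam, a) == pytest.approx(1.7 * lam / 2.7)
        assert scad_derivative(10 * a * lam, lam, a) == 0.0

    def test_derivative_continuous_at_breakpoints(self):
        lam, a = 1.3, 3.7
        for w in (lam, a * lam):
            lo = scad_derivative(w - 1e-9, lam, a)
            hi = scad_derivative(w + 1e-9, lam, a)
            assert lo == pytest.approx(hi, abs=1e-8)

    def test_negative_w_rejected(self):
        with pytest.raises(ValueError):
            scad_derivative(-0.1, 1.0)
        with pytest.raises(ValueError):
            scad_penalty(-0.1, 1.0)

    def test_penalty_anchor_values(self):
        lam, a = 0.6, 3.7
        assert scad_penalty(0.0, lam, a) == 0.0
        assert scad_penalty(lam, lam, a) == pytest.approx(lam**2)
        assert scad_penalty(a * lam, lam, a) == pytest.approx((a + 1) * lam**2 / 2)

    def test_penalty_matches_quadrature_of_derivative(self):
        lam, a = 0.9, 3.7
        for w in (0.3, 0.9, 1.7, 3.0, 4.0):
            val, _ = quad(scad_derivative, 0, w, args=(lam, a))
            assert scad_penalty(w, lam, a) == pytest.approx(val, abs=1e-8)

    def test_penalty_concave_nondecreasing(self):
        lam, a = 0.7, 3.7
        w = np.linspace(0, 4, 200)
        p = scad_penalty(w, lam, a)
        assert np.all(np.diff(p) >= -1e-12)
        assert np.all(np.diff(p, 2) <= 1e-12)


def _toy_design(rng, n=8, d=2, snr=1.0):
    s = center_two_group(
        random_sample(
            rng, n_nd=n // 2 + n % 2, n_d=n // 2, d=d, sigma=1.0,
            theta_nd=snr * rng.standard_normal(d), theta_d=snr * rng.standard_normal(d),
        )
    )
    return apply_weights(build_stacked_design(s, 1.0, 1.0))


class TestGroupScad:
    def test_lambda_zero_is_weighted_least_squares(self, rng):
        design = _toy_design(rng, n=10, d=2)
        fit = fit_group_scad(design, PenaltySpec(lam=0.0))
        wls, *_ = np.linalg.lstsq(design.design, design.response, rcond=None)
        assert np.allclose(fit.theta, wls, atol=1e-8)
        assert fit.active_groups == {0, 1}

    def test_large_lambda_zeroes_all_groups(self, rng):
        design = _toy_design(rng, n=10, d=3)
        # groupwise KKT bound computed for the orthonormalized standardization
        n = design.n
        bound = 0.0
        for cols in design.groups:
            Q, _ = np.linalg.qr(design.design[:, list(cols)])
            bound = max(bound, np.linalg.norm(np.sqrt(n) * Q.T @ design.response / n))
        fit = fit_group_scad(design, PenaltySpec(lam=bound * 1.0001))
        assert fit.active_groups == frozenset()
        assert np.allclose(fit.theta, 0)

    def test_matches_pattern_brute_force(self, rng):
        for k in range(6):
            design = _toy_design(rng, n=8, d=2, snr=0.8)
            spec = PenaltySpec(lam=0.1 + 0.15 * k)
            fit = fit_group_scad(design, spec)
            oracle = brute_force_group_scad(design, spec)
            assert fit.objective_value == pytest.approx(oracle, abs=1e-6)

    def test_group_coherence_never_splits_pairs(self, rng):
        for _ in range(10):
            design = _toy_design(rng, n=12, d=3, snr=0.5)
            fit = fit_group_scad(design, PenaltySpec(lam=0.3))
            for m, cols in enumerate(design.groups):
                pair = fit.theta[list(cols)]
                assert (np.all(pair == 0)) == (m not in fit.active_groups)

    def test_objective_value_recomputes(self, rng):
        design = _toy_design(rng, n=12, d=3)
        spec = PenaltySpec(lam=0.25)
        fit = fit_group_scad(design, spec)
        assert fit.objective_value == pytest.approx(
            penalized_objective(design, fit.theta, spec), abs=1e-8
        )
        assert fit.df == 2 * len(fit.active_groups)

    def test_requires_transformed_design(self, toy_centered):
        design = build_stacked_design(toy_centered, 1.0, 1.0)
        with pytest.raises(ValueError, match="transformed"):
            fit_group_scad(design, PenaltySpec(lam=0.1))


class TestGroupScadPath:
    def test_single_point_grid(self, rng):
        design = _toy_design(rng)
        path = group_scad_path(design, grid=np.array([0.5]))
        assert len(path.fits) == 1 and path.fits[0].lam == 0.5

    def test_default_grid_starts_empty(self, rng):
        design = _toy_design(rng, n=12, d=3)
        path = group_scad_path(design, n_grid=25)
        assert path.fits[0].active_groups == frozenset()
        assert len(path.fits) == 25
        assert np.all(np.diff(path.grid) < 0)

    def test_minimization_dominates_previous_iterate(self, rng):
        design = _toy_design(rng, n=12, d=3)
        path = group_scad_path(design, n_grid=15)
        for prev, cur, lam in zip(path.fits, path.fits[1:], path.grid[1:]):
            spec = PenaltySpec(lam=float(lam))
            carried = penalized_objective(design, prev.theta, spec)
            assert cur.objective_value <= carried + 1e-8

    def test_deterministic_active_sets(self, rng):
        design = _toy_design(rng, n=12, d=3)
        p1 = group_scad_path(design, n_grid=30)
        p2 = group_scad_path(design, n_grid=30)
        assert [f.active_groups for f in p1.fits] == [f.active_groups for f in p2.fits]
        assert all(np.array_equal(a.theta, b.theta) for a, b in zip(p1.fits, p2.fits))

    def test_unsorted_grid_rejected(self, rng):
        design = _toy_design(rng)
        with pytest.raises(ValueError, match="decreasing"):
            group_scad_path(design, grid=np.array([0.1, 0.5]))

    def test_scad_approaches_group_lasso_for_huge_a(self, rng):
        design = _toy_design(rng, n=12, d=2, snr=0.6)
        lam = 0.2
        scad_fit = group_scad_path(design, grid=np.array([lam]), a=1e6).fits[0]
        lasso_fit = group_lasso_path(design, frozenset(), grid=np.array([lam])).fits[0]
        assert np.allclose(scad_fit.theta, lasso_fit.theta, atol=1e-4)


class TestGroupLassoPath:
    def test_tau_zero_is_full_wls(self, rng):
        # well-conditioned instance so coordinate descent converges tightly
        design = _toy_design(rng, n=60, d=3)
        path = group_lasso_path(design, frozenset({0}), grid=np.array([1e-12]))
        wls, *_ = np.linalg.lstsq(design.design, design.response, rcond=None)
        assert np.allclose(path.fits[0].theta, wls, atol=1e-6)

    def test_large_tau_keeps_only_narrow(self, rng):
        design = _toy_design(rng, n=12, d=3, snr=1.5)
        path = group_lasso_path(design, frozenset({0}), n_grid=20)
        first = path.fits[0]
        assert first.active_groups <= {0}
        cols = [0, 1]
        wls, *_ = np.linalg.lstsq(design.design[:, cols], design.response, rcond=None)
        assert np.allclose(first.theta[cols], wls, atol=1e-6)
        assert np.allclose(np.delete(first.theta, cols), 0)

    def test_nested_active_sets_along_path(self, rng):
        design = _toy_design(rng, n=12, d=3, snr=1.0)
        path = group_lasso_path(design, frozenset({0}), n_grid=40)
        sizes = [len(f.active_groups) for f in path.fits]
        distinct = [f.active_groups for f in path.fits]
        for a, b in zip(distinct, distinct[1:]):
            if a != b:
                assert a <= b  # weakly nested as tau decreases

    def test_single_extension_group_soft_threshold(self, rng):
        # one extension factor, orthonormalized columns: the fitted group norm
        # is the soft-thresholded OLS group norm, max(0, 1 - tau/||g||)*||g||
        n = 12
        design = _toy_design(rng, n=n, d=1, snr=1.0)
        Q, _ = np.linalg.qr(design.design)
        design.design = np.sqrt(n) * Q  # exactly orthonormalized block
        g_ols = design.design.T @ design.response / n
        for tau in (0.05, 0.2, 0.5, 2.0):
            path = group_lasso_path(design, frozenset(), grid=np.array([tau]))
            got = np.linalg.norm(design.design @ path.fits[0].theta) / np.sqrt(n)
            want = max(0.0, np.linalg.norm(g_ols) - tau)
            assert got == pytest.approx(want, abs=1e-6)

    def test_narrow_superset_rejected(self, rng):
        design = _toy_design(rng, d=2)
        with pytest.raises(ValueError, match="subset"):
            group_lasso_path(design, frozenset({5}), grid=np.array([0.1]))


class TestSeparateScad:
    def test_lambda_zero_is_group_ols(self, rng):
        s = center_two_group(random_sample(rng, 10, 10, 2, theta_nd=[1, 0], theta_d=[0, 2]))
        fit = fit_separate_scad(s, PenaltySpec(lam=0.0), "diseased")
        ols, *_ = np.linalg.lstsq(s.z_diseased, s.y_diseased, rcond=None)
        assert np.allclose(fit.theta, ols, atol=1e-8)

    def test_one_covariate_brute_force(self, rng):
        s = center_two_group(random_sample(rng, 8, 8, 1, theta_nd=[0.7], theta_d=[0.4]))
        Z, y = s.z_nondiseased, s.y_nondiseased
        n = len(y)
        K = (Z.T @ Z / n).item()
        for lam in (0.05, 0.2, 0.6):
            spec = PenaltySpec(lam=lam)
            fit = fit_separate_scad(s, spec, "nondiseased")
            ts = np.linspace(-3, 3, 120001)
            objs = 0.5 * np.mean((y[:, None] - Z @ ts[None, :]) ** 2, axis=0) + scad_penalty(
                np.sqrt(K) * np.abs(ts), lam, spec.a
            )
            got = 0.5 * float(np.mean((y - Z @ fit.theta) ** 2)) + scad_penalty(
                np.sqrt(K) * abs(float(fit.theta[0])), lam, spec.a
            )
            assert got == pytest.approx(objs.min(), abs=1e-6)

    def test_identical_groups_identical_selection(self, rng):
        z = rng.standard_normal((10, 3))
        y = z @ np.array([1.0, 0.0, 0.5]) + 0.3 * rng.standard_normal(10)
        from rocselect.data import TwoGroupSample

        s = center_two_group(
            TwoGroupSample(y_nondiseased=y, y_diseased=y, z_nondiseased=z, z_diseased=z)
        )
        spec = PenaltySpec(lam=0.15)
        f1 = fit_separate_scad(s, spec, "nondiseased")
        f2 = fit_separate_scad(s, spec, "diseased")
        assert f1.active_groups == f2.active_groups
        assert np.allclose(f1.theta, f2.theta)

    def test_path_runs_and_is_monotone_grid(self, rng):
        s = center_two_group(random_sample(rng, 12, 12, 4, theta_nd=[2, 0, 0, 0], theta_d=[1, 1, 0, 0]))
        path = separate_scad_path(s, "diseased", n_grid=20)
        assert len(path.fits) == 20
        assert path.penalty_kind == "separate_scad"


class TestPenaltySpecValidation:
    def test_shape_constant_must_exceed_two(self):
        with pytest.raises(ValueError):
            PenaltySpec(lam=0.1, a=1.5)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            PenaltySpec(lam=-0.1)

    def test_custom_norm_matrix_must_be_spd(self):
        with pytest.raises(ValueError):
            PenaltySpec(lam=0.1, norm_matrices=[np.array([[1.0, 2.0], [2.0, 1.0]])])

    def test_custom_norm_matrices_accepted_and_used(self, rng):
        design = _toy_design(rng, n=10, d=2)
        Ks = [np.eye(2), np.eye(2)]
        fit = fit_group_scad(design, PenaltySpec(lam=0.2, norm_matrices=Ks))
        assert np.isfinite(fit.objective_value)
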