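"""Spline basis construction, penalties, prior density and Gibbs updates."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal

from hierdsm import smooths as sm
from hierdsm.smooths import (SmoothSpec, SmoothingParams, build_basis,
                             build_design, gibbs_update_gamma, predict_basis,
                             smooth_prior_logpdf)


@pytest.fixture
def x100(rng):
    return rng.uniform(-2.0, 2.0, 100)


@pytest.mark.parametrize("basis_type", ["cubic_regression", "thin_plate"])
class TestBasisConstruction:
    def test_constrained_shape_and_centering(self, x100, basis_type):
        b = build_basis(x100, SmoothSpec("x", basis_type, K=5))
        assert b.design_columns.shape == (100, 4)
        assert np.all(np.abs(b.design_columns.sum(axis=0)) < 1e-8)

    def test_penalties_positive_semidefinite(self, x100, basis_type):
        b = build_basis(x100, SmoothSpec("x", basis_type, K=6))
        for S in b.all_penalties():
            evals = np.linalg.eigvalsh(S)
            assert evals.min() >= -1e-10 * max(1.0, evals.max())

    def test_full_rank_prior_precision(self, x100, basis_type):
        b = build_basis(x100, SmoothSpec("x", basis_type, K=5))
        P = sum(b.all_penalties())
        assert np.linalg.matrix_rank(P) == b.dim

    def test_quadratic_reproduction_vs_least_squares(self, rng, basis_type):
        """Nearly unpenalized large-K fit reproduces a polynomial regression.

        Both bases penalize integrated squared curvature with piecewise-linear
        second derivatives and natural-type boundary behavior, so a quadratic
        is reproduced only up to an O(h^2) boundary layer, not exactly.
        """
        x = np.sort(rng.uniform(-1.0, 1.0, 200))
        y = 1.5 - 0.8 * x + 0.6 * x * x
        b = build_basis(x, SmoothSpec("x", basis_type, K=12))
        X = np.column_stack([np.ones(x.size), b.design_columns])
        P = np.zeros((X.shape[1], X.shape[1]))
        P[1:, 1:] = 1e-9 * (b.penalty_mats[0] + b.nullspace_penalty)
        coef = np.linalg.solve(X.T @ X + P, X.T @ y)
        fitted = X @ coef
        poly = np.polynomial.polynomial.polyvander(x, 2)
        ls = poly @ np.linalg.lstsq(poly, y, rcond=None)[0]
        assert np.max(np.abs(fitted - ls)) < 5e-3

    def test_too_few_unique_values_rejected(self, basis_type):
        with pytest.raises(ValueError, match="K"):
            build_basis(np.array([0.0, 1.0, 1.0, 0.0, 1.0]),
                        SmoothSpec("x", basis_type, K=5))


class TestPredictBasis:
    def test_training_points_identity(self, x100):
        b = build_basis(x100, SmoothSpec("x", K=5))
        assert np.array_equal(predict_basis(x100, b), b.design_columns)

    def test_single_point_at_knot_matches_direct_row(self, x100):
        b = build_basis(x100, SmoothSpec("x", K=5))
        k = b.knots[2]
        row = predict_basis(np.array([k]), b)
        full = predict_basis(np.concatenate([[k], x100]), b)
        assert np.allclose(row[0], full[0], atol=1e-12)

    def test_extrapolation_warns_and_extends_linearly(self, x100):
        b = build_basis(x100, SmoothSpec("x", K=5))
        beta = np.array([0.4, -0.2, 0.1, 0.3])
        hi = b.knots[-1]
        with pytest.warns(UserWarning, match="linear extension"):
            vals = predict_basis(np.array([hi + 0.5, hi + 1.0]), b) @ beta
        with pytest.warns(UserWarning):
            v0 = predict_basis(np.array([hi + 0.25]), b) @ beta
        f_hi = predict_basis(np.array([hi]), b) @ beta
        # equal spacing along the extension stays on one straight line
        assert vals[1] - vals[0] == pytest.approx(2 * (v0[0] - f_hi[0]), rel=1e-6)

    def test_smooth_has_zero_mean_over_training(self, rng, x100):
        b = build_basis(x100, SmoothSpec("x", K=5))
        beta = rng.normal(size=4)
        assert np.mean(b.design_columns @ beta) == pytest.approx(0.0, abs=1e-10)


class TestSmoothPrior:
    def test_zero_coefficients_closed_form(self, x100):
        b = build_basis(x100, SmoothSpec("x", K=5))
        g = SmoothingParams([2.0, 3.0])
        P = 2.0 * b.penalty_mats[0] + 3.0 * b.nullspace_penalty
        expected = 0.5 * np.linalg.slogdet(P)[1] - 2.0 * np.log(2 * np.pi)
        assert smooth_prior_logpdf(np.zeros(4), b, g) == pytest.approx(expected, abs=1e-10)

    def test_matches_dense_mvn_oracle(self, rng, x100):
        b = build_basis(x100, SmoothSpec("x", K=6))
        g = SmoothingParams([0.7, 5.0])
        P = 0.7 * b.penalty_mats[0] + 5.0 * b.nullspace_penalty
        cov = np.linalg.inv(P)
        for _ in range(5):
            beta = rng.normal(size=b.dim)
            oracle = multivariate_normal(mean=np.zeros(b.dim), cov=cov).logpdf(beta)
            assert smooth_prior_logpdf(beta, b, g) == pytest.approx(oracle, abs=1e-10)

    def test_gamma_doubling_shift_identity_penalty(self, rng):
        """With S = I penalties, doubling gamma shifts logpdf by d/2 log2 - beta'beta/2."""
        x = rng.uniform(0, 1, 50)
        b = build_basis(x, SmoothSpec("x", K=5))
        d = b.dim
        b.penalty_mats = [np.eye(d)]
        b.nullspace_penalty = np.zeros((d, d))
        b.penalty_ranks = np.array([d, 0])
        beta = rng.normal(size=d)
        lp1 = smooth_prior_logpdf(beta, b, SmoothingParams([1.0, 1.0]))
        lp2 = smooth_prior_logpdf(beta, b, SmoothingParams([2.0, 2.0]))
        assert lp2 - lp1 == pytest.approx(d / 2 * np.log(2) - 0.5 * beta @ beta, abs=1e-10)


class TestGibbsGamma:
    def test_zero_coefficients_draw_from_rank_adjusted_prior(self, x100):
        b = build_basis(x100, SmoothSpec("x", K=5))
        rng = np.random.default_rng(0)
        draws = np.array([gibbs_update_gamma(np.zeros(4), b, rng=rng).gamma_k
                          for _ in range(20000)])
        r_main = b.penalty_ranks[0]
        assert draws[:, 0].mean() == pytest.approx(
            (0.05 + r_main / 2) / 0.005, rel=0.03)

    def test_monte_carlo_mean_matches_conjugate_algebra(self, rng, x100):
        b = build_basis(x100, SmoothSpec("x", K=5))
        beta = rng.normal(size=4)
        quads = [beta @ S @ beta for S in b.all_penalties()]
        g = np.array([gibbs_update_gamma(beta, b, rng=rng).gamma_k
                      for _ in range(100_000)])
        for k, (S, rk, q) in enumerate(zip(b.all_penalties(), b.penalty_ranks, quads)):
            analytic = (0.05 + rk / 2) / (0.005 + q / 2)
            assert g[:, k].mean() == pytest.approx(analytic, rel=0.01)

    def test_full_conditional_density_by_quadrature(self, x100):
        """Full-conditional of gamma is proportional to prior x MVN normalizer."""
        b = build_basis(x100, SmoothSpec("x", K=5))
        rng = np.random.default_rng(3)
        for _ in range(3):
            beta = rng.normal(scale=0.5, size=4)
            q = float(beta @ b.penalty_mats[0] @ beta)
            rk = b.penalty_ranks[0]
            a_post, b_post = 0.05 + rk / 2, 0.005 + q / 2

            def unnorm(g):
                # prior density x the gamma-dependent part of the MVN normalizer
                return g ** (0.05 - 1 + rk / 2) * np.exp(-0.005 * g - 0.5 * q * g)

            norm, _ = quad(unnorm, 0, np.inf)
            mean_quad, _ = quad(lambda g: g * unnorm(g) / norm, 0, np.inf)
            assert mean_quad == pytest.approx(a_post / b_post, rel=1e-6)

    def test_gamma_prior_mean_is_ten(self):
        a, b = sm.GAMMA_PRIOR
        assert a / b == pytest.approx(10.0)


def test_shrinkage_monotone_in_gamma(rng):
    """Penalized fit norm decreases monotonically along a gamma ladder."""
    x = np.sort(rng.uniform(-1, 1, 150))
    y = np.sin(2.5 * x) + rng.normal(scale=0.3, size=x.size)
    b = build_basis(x, SmoothSpec("x", K=8))
    X = b.design_columns
    norms = []
    for g in [0.01, 1.0, 100.0, 10000.0]:
        P = g * (b.penalty_mats[0] + b.nullspace_penalty)
        beta = np.linalg.solve(X.T @ X + P, X.T @ (y - y.mean()))
        norms.append(np.linalg.norm(X @ beta))
    assert all(a > b_ for a, b_ in zip(norms, norms[1:]))


def test_build_design_assembles_intercept_and_terms(rng):
    covs = {"a": rng.uniform(0, 1, 60), "b": rng.normal(size=60)}
    specs = [SmoothSpec("a", K=5), SmoothSpec("b", K=4)]
    d = build_design(covs, specs)
    assert d.X.shape == (60, 1 + 4 + 3)
    assert np.all(d.X[:, 0] == 1.0)
    Xp = d.predict(covs)
    assert np.allclose(Xp, d.X, atol=1e-10)
    with pytest.raises(KeyError, match="missing"):
        build_design({"a": covs["a"]}, specs)
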