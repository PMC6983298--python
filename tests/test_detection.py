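"""Detection-function closed forms, likelihood oracles and ML recovery."""

import numpy as np
import pytest
from scipy.special import expit

from hierdsm import detection as det
from hierdsm.detection import (DetectionParams, SightingArrays,
                               beta_from_mean_cv, detection_loglik, esw,
                               fit_mrds_ml, key_prob, theta, trackline_prob)


def hn(sigma=1.0):
    return DetectionParams(key="half_normal", log_sigma_coefs=[np.log(sigma)],
                           mr_coefs=[0.0, 0.0])


def hr(sigma=1.0, b=2.0):
    return DetectionParams(key="hazard_rate", log_sigma_coefs=[np.log(sigma)],
                           log_b=np.log(b), mr_coefs=[0.0, 0.0])


class TestKeyProb:
    def test_half_normal_closed_form(self):
        assert key_prob(0.0, None, hn(1.0)) == 1.0
        assert key_prob(1.0, None, hn(1.0)) == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_hazard_rate_trackline_limit(self):
        assert key_prob(0.0, None, hr(0.3, 3.0)) == 1.0

    @pytest.mark.parametrize("params", [hn(0.7), hr(0.5, 2.5)])
    def test_monotone_nonincreasing_and_bounded(self, params):
        y = np.linspace(0.0, 3.0, 200)
        g = key_prob(y, None, params)
        assert np.all(np.diff(g) <= 1e-12)
        assert np.all((g > 0) & (g <= 1))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            key_prob(-0.1, None, hn())


class TestEsw:
    def test_half_normal_closed_form(self):
        # sigma sqrt(pi/2) erf(W / (sigma sqrt 2)) at sigma=1, W=2
        assert esw(hn(1.0), None, 2.0) == pytest.approx(1.1962880133, abs=1e-9)

    def test_degenerate_scale_limit(self):
        assert esw(hn(1e-6), None, 1.0) < 1e-5

    def test_analytic_matches_quadrature_on_grid(self):
        for sigma in (0.2, 0.5, 1.0, 2.5):
            for W in (0.5, 1.0, 3.0, 6.0):
                a = esw(hn(sigma), None, W)
                q = esw(hn(sigma), None, W, force_quadrature=True)
                assert a == pytest.approx(q, abs=1e-10)

    def test_hazard_rate_vs_dense_trapezoid(self):
        p = hr(0.5, 2.5)
        W = 1.5
        y = np.linspace(0, W, 1_000_001)
        g = np.atleast_1d(key_prob(y, None, p))
        oracle = np.trapezoid(g, y)
        assert esw(p, None, W) == pytest.approx(oracle, abs=1e-8)

    def test_result_bounded_by_strip(self):
        assert 0 < esw(hr(0.4, 2.0), None, 1.0) <= 1.0


class TestTracklineAndTheta:
    def test_independent_two_observer_removal(self):
        assert trackline_prob(None, 0.0, hn(), "independent") == pytest.approx(0.75)

    def test_trial_configuration(self):
        assert trackline_prob(None, 0.0, hn(), "trial") == pytest.approx(0.5)

    def test_theta_identity_when_perfect(self):
        p = DetectionParams(key="half_normal", log_sigma_coefs=[np.log(1e6)],
                            mr_coefs=[50.0, 0.0])
        assert theta(None, p, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_theta_reported_shipboard_product(self):
        # distance component 0.36 with g(0) 0.66 gives theta = 0.2376
        assert 0.36 * 0.66 == pytest.approx(0.2376, abs=1e-12)

    def test_theta_monotone_in_scale(self):
        W = 2.0
        vals = [theta(None, hn(s), W) for s in np.linspace(0.1, 3.0, 12)]
        assert np.all(np.diff(vals) > 0)

    def test_theta_bounded_by_g0(self):
        p = DetectionParams(key="half_normal", log_sigma_coefs=[0.0],
                            mr_coefs=[0.4, -0.3])
        g0 = trackline_prob(None, 0.0, p, "independent")
        assert theta(None, p, 2.0) <= min(1.0, g0)


class TestEffectiveP:
    def test_ship_identity(self):
        assert det.effective_p("ship", 0.25, 0.37) == 0.25

    def test_aerial_availability_product(self):
        # aerial detection components 0.47 x 0.67 with availability 0.37
        th = 0.47 * 0.67
        assert det.effective_p("aerial", th, 0.37) == pytest.approx(0.116513, abs=1e-5)

    def test_full_availability_reduces_to_ship(self):
        assert det.effective_p("aerial", 0.3, 1.0) == det.effective_p("ship", 0.3, 1.0)

    def test_effective_p_never_exceeds_theta(self, rng):
        th = rng.uniform(0.01, 1.0, 50)
        a = rng.uniform(0.01, 1.0, 50)
        assert np.all(det.effective_p("aerial", th, a) <= th + 1e-15)


class TestBetaPrior:
    def test_matches_availability_prior(self):
        p = beta_from_mean_cv(0.37, 0.34)
        assert p.alpha == pytest.approx(5.079827, abs=1e-4)
        assert p.beta == pytest.approx(8.649435, abs=1e-4)

    @pytest.mark.parametrize("mean,cv", [(0.37, 0.34), (0.67, 0.16), (0.05, 0.9),
                                         (0.9, 0.05)])
    def test_round_trip_moments(self, mean, cv):
        p = beta_from_mean_cv(mean, cv)
        assert p.mean == pytest.approx(mean, abs=1e-10)
        assert p.cv == pytest.approx(cv, abs=1e-10)

    def test_variance_too_large_rejected(self):
        with pytest.raises(ValueError):
            beta_from_mean_cv(0.5, 2.0)

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ValueError):
            beta_from_mean_cv(0.5, 1e-6)


def _arrays(y, omega, k=0):
    n = len(y)
    return SightingArrays(y=np.asarray(y, dtype=float),
                          omega=np.asarray(omega, dtype=int).reshape(n, 2),
                          scale_covs=np.zeros((n, k)), mr_covs=np.zeros((n, k)))


class TestDetectionLoglik:
    def test_brute_force_product_oracle(self):
        """Sum over records equals the per-record log product computed directly."""
        p = DetectionParams(key="half_normal", log_sigma_coefs=[np.log(0.8)],
                            mr_coefs=[0.6, -0.4])
        y = [0.1, 0.5, 0.9, 1.3, 0.2]
        om = [(1, 1), (1, 0), (0, 1), (1, 1), (1, 0)]
        W = 1.5
        arr = _arrays(y, om)
        mu = esw(p, None, W)
        expected = 0.0
        for yy, (w1, w2) in zip(y, om):
            g = np.exp(-0.5 * (yy / 0.8) ** 2)
            pc = expit(0.6 - 0.4 * yy)
            denom = 1.0 - (1.0 - pc) ** 2
            hist = pc ** (w1 + w2) * (1 - pc) ** (2 - w1 - w2) / denom
            expected += np.log(g / mu) + np.log(hist)
        got = detection_loglik(arr, p, W, "independent")
        assert got == pytest.approx(expected, abs=1e-10)

    def test_certain_observers_capture_term_vanishes(self):
        p = DetectionParams(key="half_normal", log_sigma_coefs=[0.0],
                            mr_coefs=[40.0, 0.0])
        arr = _arrays([0.0], [(1, 1)])
        full = detection_loglik(arr, p, 50.0, "independent")
        dist_only = detection_loglik(arr, p, 50.0, include_capture=False)
        assert full == pytest.approx(dist_only, abs=1e-8)

    def test_sigma_grid_recovery(self, rng):
        """Maximizing over a scale grid recovers the generating scale within 10%."""
        sigma_true, W, n = 0.8, 2.0, 500
        y = []
        while len(y) < n:
            c = rng.uniform(0, W)
            if rng.random() < np.exp(-0.5 * (c / sigma_true) ** 2):
                y.append(c)
        arr = _arrays(y, [(1, 0)] * n)
        grid = np.linspace(0.3, 1.6, 131)
        lls = [detection_loglik(arr, hn(s), W, include_capture=False) for s in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(sigma_true, rel=0.10)


class TestFitMrdsMl:
    def test_requires_enough_sightings(self):
        with pytest.raises(ValueError):
            fit_mrds_ml(_arrays([0.1] * 5, [(1, 0)] * 5), W=1.0)

    def test_half_normal_simulation_recovery(self):
        """ML estimate of log sigma lands within 2 SE of the truth in >= 90% of replicates."""
        sigma_true, W, n = 0.8, 2.0, 300
        delta = np.array([1.0, -0.4])
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            y = []
            while len(y) < n:
                c = rng.uniform(0, W, 4 * n)
                y.extend(c[rng.random(c.size) < np.exp(-0.5 * (c / sigma_true) ** 2)])
            y = np.array(y[:n])
            pc = expit(delta[0] + delta[1] * y)
            om = []
            for p in pc:
                d = 1 - (1 - p) ** 2
                u = rng.random()
                om.append((1, 1) if u < p * p / d
                          else ((1, 0) if u < (p * p + p * (1 - p)) / d else (0, 1)))
            params, cov, _ = fit_mrds_ml(_arrays(y, om), key="half_normal",
                                         configuration="independent", W=W)
            se = np.sqrt(cov[0, 0])
            if abs(params.log_sigma_coefs[0] - np.log(sigma_true)) < 2 * se:
                hits += 1
        assert hits / n_rep >= 0.9

    def test_summary_reports_detection_components(self, small_survey):
        design, _, _, sightings = small_survey
        arr = SightingArrays.from_records(
            [s for s in sightings if s.platform == "ship"])
        params, _, summ = fit_mrds_ml(arr, key="half_normal", W=design.trunc_W_km)
        assert 0 < summ["mean_pd"] <= 1
        assert 0 < summ["mean_g0"] <= 1
        assert summ["mean_theta"] == pytest.approx(
            summ["mean_pd"] * summ["mean_g0"], rel=1e-9)
        assert summ["mean_pd_cv"] > 0
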