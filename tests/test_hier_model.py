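"""Joint posterior assembly, sampler correctness and diagnostics."""

import math

import numpy as np
import pytest

from hierdsm import cpg as cpg_mod
from hierdsm import group_size as gs_mod
from hierdsm.detection import DetectionParams, beta_from_mean_cv
from hierdsm.hier_model import (FixSpec, ModelData, PosteriorDraws,
                                effective_sample_size, gelman_rubin,
                                joint_logpost, logpost_terms,
                                posterior_summary, run_mcmc)
from hierdsm.survey_io import CellRecord, StudyConfig


def _one_cell(n_groups=2.0):
    return CellRecord(cell_id="c0", platform="ship", period_id="p",
                      effort_km=10.0, trunc_W_km=1.0, searched_area_km2=20.0,
                      cell_area_km2=100.0, n_groups=n_groups)


def _tiny_config(**kw):
    defaults = dict(smooths=[], truncation={"ship": 1.0, "aerial": 0.3},
                    key_ship="half_normal", key_aerial="half_normal",
                    n_chains=1, n_iter=400, n_burn=100, thin=1)
    defaults.update(kw)
    return StudyConfig(**defaults)


def _state_for(data, **kw):
    from hierdsm.hier_model import ModelState
    defaults = dict(
        beta=np.array([-1.0]), phi=np.array([0.3]), log_alpha=0.1,
        gammas=np.zeros(0), lambda_s=0.4,
        det_ship=DetectionParams(key="half_normal",
                                 log_sigma_coefs=[np.log(0.5)],
                                 mr_coefs=[1.0, -0.4]),
        det_aerial=DetectionParams(key="half_normal",
                                   log_sigma_coefs=[np.log(0.15)],
                                   g0_source="external", g0_external=0.67),
        availability=0.37, g0_aerial=0.67,
        G=np.where(data.Y > 0, np.ceil(data.Y), 0).astype(np.int64))
    defaults.update(kw)
    return ModelState(**defaults)


class TestJointLogpost:
    def test_no_data_equals_sum_of_priors(self):
        cfg = _tiny_config()
        data = ModelData([], [], cfg)
        state = _state_for(data, beta=np.zeros(1), G=np.zeros(0, dtype=np.int64))
        terms = logpost_terms(state, data)
        assert terms["cpg"] == 0.0
        assert terms["det_ship"] == 0.0
        assert terms["group_size"] == 0.0
        prior_sum = (terms["coef_prior"] + terms["detection_prior"]
                     + terms["availability_prior"] + terms["lambda_s_prior"]
                     + terms["smooth_prior"])
        assert joint_logpost(state, data) == pytest.approx(prior_sum)

    def test_single_cell_component_sum_oracle(self):
        """The joint decomposes into exactly the augmented CPG term plus priors."""
        cfg = _tiny_config()
        data = ModelData([_one_cell(2.0)], [], cfg)
        state = _state_for(data)
        terms = logpost_terms(state, data)

        from hierdsm.detection import theta as theta_fn
        p = theta_fn(None, state.det_ship, 1.0)
        off = math.log(p * 20.0)
        lp = math.exp(0.5 * (state.beta[0] - state.phi[0]) + off)
        lg = math.exp(0.5 * (state.beta[0] + state.phi[0]))
        expected_cpg = cpg_mod.cpg_loglik_aug(2.0, 2, lp, lg, math.exp(0.1))
        assert terms["cpg"] == pytest.approx(expected_cpg, abs=1e-10)
        assert joint_logpost(state, data) == pytest.approx(sum(terms.values()))

    def test_density_shape_monotone_in_count(self):
        """Raising the count below the mean lowers the log-posterior density."""
        cfg = _tiny_config()
        lps = []
        for n in (0.0, 1.0, 2.0):
            data = ModelData([_one_cell(n)], [], cfg)
            state = _state_for(data, beta=np.array([3.0]))  # E(n) far above 2
            state.G = np.array([int(n)], dtype=np.int64)
            lps.append(logpost_terms(state, data)["cpg"])
        assert lps[0] < lps[1] < lps[2]

    def test_frozen_components_contribute_constants(self):
        cfg = _tiny_config()
        data = ModelData([_one_cell()], [], cfg)
        state = _state_for(data)
        fix = FixSpec(frozenset({"availability", "lambda_s"}), {})
        terms = logpost_terms(state, data, fix)
        assert terms["availability_prior"] == 0.0
        assert terms["lambda_s_prior"] == 0.0


class TestRunMcmc:
    def test_prior_only_recovers_availability_prior(self):
        """With no data the availability posterior is its beta prior."""
        cfg = _tiny_config(n_iter=6000, n_burn=1000, thin=1, n_chains=1)
        draws = run_mcmc([], [], cfg, seed=5)
        a = draws.pooled("availability")
        prior = beta_from_mean_cv(cfg.availability_mean, cfg.availability_cv)
        sd = prior.source_mean * prior.source_cv
        ess = effective_sample_size(a)
        mc_se = sd / np.sqrt(max(ess, 1.0))
        assert a.mean() == pytest.approx(0.37, abs=3 * mc_se + 1e-9)
        assert a.std() == pytest.approx(sd, rel=0.25)

    def test_conjugate_lambda_s_submodel(self, small_survey):
        """With everything else fixed, lambda_s matches its analytic posterior."""
        design, _, cells, sightings = small_survey
        cfg = _tiny_config(n_iter=3000, n_burn=500)
        fix = FixSpec(frozenset({"availability", "all_detection"}), {
            "availability": 1.0,
            "detection_ship": design.detection_params("ship"),
            "detection_aerial": design.detection_params("aerial")})
        draws = run_mcmc(cells, sightings, cfg, fix=fix, seed=3)
        lam = draws.pooled("lambda_s")
        sizes = np.array([s.group_size for s in sightings])
        a_post = 0.01 + np.sum(sizes - 1)
        b_post = 0.01 + sizes.size
        assert lam.mean() == pytest.approx(a_post / b_post, rel=0.01)

    def test_same_seed_identical_draws(self, small_survey):
        design, _, cells, sightings = small_survey
        cfg = _tiny_config(n_iter=300, n_burn=100,
                           smooths=[{"covariate_name": design.covariate_name,
                                     "K": 4}])
        d1 = run_mcmc(cells, sightings, cfg, seed=17)
        d2 = run_mcmc(cells, sightings, cfg, seed=17)
        for nm in d1.names:
            assert np.array_equal(d1.get(nm), d2.get(nm))

    def test_detection_covariates_enter_scale_and_mr_models(self, rng):
        """Named detection-condition covariates add coefficients to both
        the log-scale model and the conditional-detection logistic."""
        from hierdsm.survey_io import SightingRecord
        cells, sights = [], []
        for i in range(40):
            bf = float(rng.integers(0, 4))
            n = int(rng.poisson(1.0))
            cells.append(CellRecord(
                cell_id=f"c{i}", platform="ship", period_id="p",
                effort_km=10.0, trunc_W_km=1.0, searched_area_km2=20.0,
                cell_area_km2=100.0, n_groups=n,
                detect_covs={"beaufort": bf}))
            for k in range(n):
                sights.append(SightingRecord(
                    sight_id=f"s{i}.{k}", cell_id=f"c{i}", platform="ship",
                    distance_km=float(rng.uniform(0, 1)), capture=(1, 1),
                    group_size=1, detect_covs={"beaufort": bf}))
        cfg = _tiny_config(detect_cov_names=["beaufort"], n_iter=200, n_burn=80)
        draws = run_mcmc(cells, sights, cfg, seed=1)
        assert "ship.log_sigma.1" in draws.names
        assert "ship.delta.2" in draws.names

    def test_retained_draw_count_contract(self, small_survey):
        design, _, cells, sightings = small_survey
        cfg = _tiny_config(n_iter=500, n_burn=200, thin=3, n_chains=2)
        draws = run_mcmc(cells, sightings, cfg, seed=2)
        assert draws.shape == (2, (500 - 200) // 3)


class TestGewekeStyleConditionals:
    def test_successive_conditional_sampling_preserves_prior(self):
        """Alternating parameter draws and data draws keeps the conjugate
        pieces distributed as their priors (Geweke-style check on a toy model)."""
        rng = np.random.default_rng(8)
        prior = (2.0, 3.0)
        lam = rng.gamma(prior[0], 1.0 / prior[1])
        kept = []
        for _ in range(6000):
            sizes = 1 + rng.poisson(lam, 6)           # data | parameter
            lam = gs_mod.gibbs_update_lambda_s(sizes, prior=prior, rng=rng)
            kept.append(lam)
        from scipy.stats import gamma as gamma_dist, kstest
        stat = kstest(np.array(kept[100:])[::4],
                      gamma_dist(a=2.0, scale=1 / 3.0).cdf).statistic
        assert stat < 0.05


class TestGelmanRubin:
    def _draws_from(self, chains):
        arr = np.asarray(chains, dtype=float)
        return PosteriorDraws(names=["x"], values={"x": arr})

    def test_identical_half_chains_give_unity(self, rng):
        half = rng.normal(size=500)
        chain = np.concatenate([half, half])
        rhat = gelman_rubin(self._draws_from([chain, chain]), "x")
        assert rhat <= 1.0 + 1e-6

    def test_same_distribution_near_one(self, rng):
        chains = rng.normal(size=(2, 5000))
        assert gelman_rubin(self._draws_from(chains), "x") < 1.05

    def test_separated_chains_detected(self, rng):
        c1 = rng.normal(0.0, 1.0, 1000)
        c2 = rng.normal(10.0, 1.0, 1000)
        assert gelman_rubin(self._draws_from([c1, c2]), "x") > 3.0

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(self._draws_from(rng.normal(size=(1, 100))), "x")


class TestPosteriorSummary:
    def test_constant_chain(self):
        s = posterior_summary(np.full(100, 3.0))
        assert (s["mean"], s["sd"], s["cv"]) == (3.0, 0.0, 0.0)

    def test_matches_draw_file_recomputation(self, tmp_path, rng):
        from hierdsm.survey_io import read_draws, write_draws
        d = PosteriorDraws(names=["p"], values={"p": rng.normal(2.0, 0.3, (2, 400))})
        write_draws(d, tmp_path / "d.csv")
        back = read_draws(tmp_path / "d.csv")
        s1 = posterior_summary(d, "p")
        s2 = posterior_summary(back, "p")
        assert s1 == s2

    def test_standard_normal_interval(self, rng):
        x = rng.normal(size=200_000)
        s = posterior_summary(x + 10.0)
        assert s["q2.5"] - 10 == pytest.approx(-1.96, abs=0.03)
        assert s["q97.5"] - 10 == pytest.approx(1.96, abs=0.03)

    def test_sign_changing_cv_error_when_required(self, rng):
        with pytest.raises(ValueError, match="CV"):
            posterior_summary(rng.normal(size=1000), require_cv=True)
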