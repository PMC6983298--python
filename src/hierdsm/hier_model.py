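"""Joint posterior assembly and MCMC for the one-stage hierarchical model.

The expected number of groups sighted in analysis unit i is

    E(n_i) = p_i A_i exp(B0 + sum_j f_j(X_ij)),

where p_i is the survey-specific detection probability (theta_i for ship,
theta_i * a for aerial; theta_i the point-independence estimator evaluated at
cell-level detection conditions), A_i the searched area, and the f_j are
penalized spline smooths of habitat covariates.  Counts follow the compound
Poisson-gamma likelihood with latent-count augmentation; the detection
parameters are informed simultaneously by the per-sighting distance and
capture-history likelihood; group sizes follow the shifted Poisson model.

Sampling is blockwise: exact Gibbs updates for the smoothing parameters
gamma_k, the group-size rate lambda_s, and the latent counts G_i; adaptive
random-walk Metropolis (target acceptance 0.3, adaptation frozen after
burn-in) for the regression coefficients, the split-coefficient phi, the
detection parameters, logit availability, logit aerial g(0) and log alpha.
Any subset of first-stage components can be frozen at point values
(:class:`FixSpec`) for the variance-component analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, gammaln, logit

from . import cpg as cpg_mod
from . import detection as det_mod
from . import group_size as gs_mod
from . import smooths as sm_mod
from .detection import DetectionParams, SightingArrays, beta_from_mean_cv
from .survey_io import StudyConfig

__all__ = [
    "ModelState", "PosteriorDraws", "FixSpec", "ModelData",
    "joint_logpost", "logpost_terms", "run_mcmc", "gelman_rubin",
    "posterior_summary", "effective_sample_size",
]

VAGUE_SD = 10.0           # N(0, 10^2) prior on all unbounded coefficients
# The continuous CPG density evaluated at integer counts is unbounded as
# alpha -> inf (the Tweedie power approaches the Poisson boundary rho -> 1 and
# the per-event gamma collapses onto the integers), which freezes the
# regression blocks.  The log-normal prior on alpha is therefore truncated to
# alpha <= ALPHA_MAX, i.e. rho >= 1.17; for genuinely continuous responses
# the bound is essentially never active.
ALPHA_MAX = 5.0


def _scalar(v) -> float:
    return float(np.asarray(v).reshape(-1)[0])
_TARGET_ACCEPT = 0.3
FIXABLE = ("lambda_s", "availability", "detection_ship", "detection_aerial",
           "all_detection")


# ---------------------------------------------------------------------------
# containers

@dataclass
class FixSpec:
    """Set of first-stage components frozen at point values."""

    components: frozenset = frozenset()
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        comps = set(self.components)
        if "all" in comps:
            comps = {"lambda_s", "availability", "all_detection"}
        if "all_detection" in comps:
            comps |= {"detection_ship", "detection_aerial"}
            comps.discard("all_detection")
        unknown = comps - {"lambda_s", "availability", "detection_ship",
                           "detection_aerial"}
        if unknown:
            raise ValueError(f"unknown fix components {sorted(unknown)}")
        self.components = frozenset(comps)

    def frozen(self, name: str) -> bool:
        return name in self.components

    @classmethod
    def none(cls) -> "FixSpec":
        return cls()


@dataclass
class PosteriorDraws:
    """Labeled store of retained MCMC draws, indexed (chain, iteration)."""

    names: list
    values: dict                      # name -> (n_chains, n_draws)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        a = next(iter(self.values.values()))
        return a.shape

    @property
    def n_retained(self) -> int:
        s = self.shape
        return s[0] * s[1]

    def get(self, name: str) -> np.ndarray:
        return self.values[name]

    def pooled(self, name: str) -> np.ndarray:
        return self.values[name].reshape(-1)

    def stack(self, names: Sequence[str]) -> np.ndarray:
        """Pooled draws of several parameters as an (n_retained, k) matrix."""
        return np.column_stack([self.pooled(n) for n in names])


@dataclass
class ModelState:
    """One point in the joint parameter space."""

    beta: np.ndarray                   # intercept + smooth coefficients
    phi: np.ndarray                    # split coefficients (same length)
    log_alpha: float
    gammas: np.ndarray                 # 2 per smooth term (main, nullspace)
    lambda_s: float
    det_ship: DetectionParams
    det_aerial: DetectionParams
    availability: float
    g0_aerial: float
    G: np.ndarray                      # latent counts per modeled cell

    def copy(self) -> "ModelState":
        return ModelState(
            beta=self.beta.copy(), phi=self.phi.copy(),
            log_alpha=self.log_alpha, gammas=self.gammas.copy(),
            lambda_s=self.lambda_s,
            det_ship=replace(self.det_ship), det_aerial=replace(self.det_aerial),
            availability=self.availability, g0_aerial=self.g0_aerial,
            G=self.G.copy())


class ModelData:
    """Preprocessed arrays the likelihood consumes."""

    def __init__(self, cells: Iterable, sightings: Iterable, config: StudyConfig):
        cells = [c for c in cells
                 if c.effort_km > 0 and c.searched_area_km2 > 0]
        self.config = config
        self.n_cells = len(cells)
        self.Y = np.array([c.n_groups for c in cells], dtype=float)
        self.A = np.array([c.searched_area_km2 for c in cells], dtype=float)
        self.W = np.array([c.trunc_W_km for c in cells], dtype=float)
        self.platform = np.array([c.platform for c in cells])
        self.ship_mask = self.platform == "ship"
        self.aer_mask = ~self.ship_mask
        cov_names = list(config.detect_cov_names)
        self.det_cov_names = cov_names
        self.Zdet = np.array(
            [[c.detect_covs.get(k, 0.0) for k in cov_names] for c in cells],
            dtype=float).reshape(self.n_cells, len(cov_names))
        if config.smooths and self.n_cells:
            hab = {s.covariate_name:
                   np.array([c.habitat_covs[s.covariate_name] for c in cells])
                   for s in config.smooths}
            self.design = sm_mod.build_design(hab, config.smooths)
        else:
            self.design = sm_mod.DesignInfo(
                X=np.ones((self.n_cells, 1)), bases=[], slices=[])
        sights = list(sightings)
        self.sizes = np.array([s.group_size for s in sights], dtype=float)
        self.ship_sights = SightingArrays.from_records(
            [s for s in sights if s.platform == "ship"], cov_names, cov_names)
        self.aer_sights = SightingArrays.from_records(
            [s for s in sights if s.platform == "aerial"], cov_names, cov_names)

    @property
    def n_coef(self) -> int:
        return self.design.n_coef


# ---------------------------------------------------------------------------
# log-posterior pieces

def _normal_logpdf(x, sd=VAGUE_SD) -> float:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return float(np.sum(-0.5 * (x / sd) ** 2 - 0.5 * np.log(2 * np.pi) - np.log(sd)))


def _gamma_logpdf(x, shape, rate) -> float:
    if x <= 0:
        return -np.inf
    return float(shape * np.log(rate) + (shape - 1) * np.log(x) - rate * x
                 - math.lgamma(shape))


def _cell_detect_p(state: ModelState, data: ModelData) -> np.ndarray:
    """Per-cell detection probability: theta_i for ship, theta_i * a for aerial."""
    p = np.empty(data.n_cells)
    for mask, params, platform in (
            (data.ship_mask, state.det_ship, "ship"),
            (data.aer_mask, state.det_aerial, "aerial")):
        if not np.any(mask):
            continue
        z = data.Zdet[mask] if data.Zdet.shape[1] else None
        th = det_mod.theta(z, params, data.W[mask])
        th = np.atleast_1d(th)
        a = state.availability if platform == "aerial" else 1.0
        p[mask] = np.clip(th, 1e-300, 1.0) * a
    return p


def _cpg_lambdas(state: ModelState, data: ModelData, log_off: np.ndarray):
    eta_b = data.design.X @ state.beta
    eta_p = data.design.X @ state.phi
    mode = data.config.offset_mode
    if mode == "poisson":
        ap = 0.5 * (eta_b - eta_p) + log_off
        ag = 0.5 * (eta_b + eta_p)
    else:
        ap = 0.5 * (eta_b - eta_p + log_off)
        ag = 0.5 * (eta_b + eta_p + log_off)
    if ap.size and (np.max(np.abs(ap)) > 700 or np.max(np.abs(ag)) > 700):
        return None, None
    return np.exp(ap), np.exp(ag)


def logpost_terms(state: ModelState, data: ModelData, fix: FixSpec | None = None) -> dict:
    """All additive components of the joint log-posterior, by name.

    Frozen components contribute constants and are reported as 0.
    """
    fix = fix or FixSpec.none()
    cfg = data.config
    terms = {}

    # count likelihood with augmented latent counts
    if data.n_cells:
        p = _cell_detect_p(state, data)
        log_off = np.log(p * data.A)
        lp, lg = _cpg_lambdas(state, data, log_off)
        if lp is None:
            terms["cpg"] = -np.inf
        else:
            terms["cpg"] = cpg_mod.cpg_loglik_aug_vec(
                data.Y, state.G, lp, lg, math.exp(state.log_alpha))
    else:
        terms["cpg"] = 0.0

    # detection likelihoods
    terms["det_ship"] = det_mod.detection_loglik(
        data.ship_sights, state.det_ship, cfg.truncation["ship"],
        configuration="independent")
    terms["det_aerial"] = det_mod.detection_loglik(
        data.aer_sights, state.det_aerial, cfg.truncation["aerial"],
        configuration="trial", include_capture=False)

    # group size
    terms["group_size"] = (gs_mod.ztp_loglik(data.sizes, state.lambda_s)
                           if data.sizes.size else 0.0)

    # priors
    smooth_lp = 0.0
    for j, (basis, sl) in enumerate(zip(data.design.bases, data.design.slices)):
        g = sm_mod.SmoothingParams(state.gammas[2 * j: 2 * j + 2])
        smooth_lp += sm_mod.smooth_prior_logpdf(state.beta[sl], basis, g)
        a0, b0 = sm_mod.GAMMA_PRIOR
        smooth_lp += sum(_gamma_logpdf(gk, a0, b0) for gk in g.gamma_k)
    terms["smooth_prior"] = smooth_lp
    alpha_prior = (_normal_logpdf(state.log_alpha)
                   if state.log_alpha <= math.log(ALPHA_MAX) else -np.inf)
    terms["coef_prior"] = (_normal_logpdf(state.beta[0])
                           + _normal_logpdf(state.phi)
                           + alpha_prior)
    det_prior = 0.0
    if not fix.frozen("detection_ship"):
        det_prior += _normal_logpdf(state.det_ship.log_sigma_coefs)
        det_prior += _normal_logpdf(state.det_ship.mr_coefs)
        if state.det_ship.key == "hazard_rate":
            det_prior += _normal_logpdf(state.det_ship.log_b)
    if not fix.frozen("detection_aerial"):
        det_prior += _normal_logpdf(state.det_aerial.log_sigma_coefs)
        if state.det_aerial.key == "hazard_rate":
            det_prior += _normal_logpdf(state.det_aerial.log_b)
        g0p = beta_from_mean_cv(cfg.g0_aerial_mean, cfg.g0_aerial_cv)
        det_prior += g0p.logpdf(state.g0_aerial)
    terms["detection_prior"] = det_prior
    if not fix.frozen("availability"):
        ap = beta_from_mean_cv(cfg.availability_mean, cfg.availability_cv)
        terms["availability_prior"] = float(ap.logpdf(state.availability))
    else:
        terms["availability_prior"] = 0.0
    if not fix.frozen("lambda_s"):
        terms["lambda_s_prior"] = _gamma_logpdf(state.lambda_s, *gs_mod.ZTP_PRIOR)
    else:
        terms["lambda_s_prior"] = 0.0
    return terms


def joint_logpost(state: ModelState, data: ModelData, fix: FixSpec | None = None) -> float:
    """Sum of all log-posterior components; -inf on zero-probability states."""
    return float(sum(logpost_terms(state, data, fix).values()))


# ---------------------------------------------------------------------------
# the sampler

class _Block:
    """One adaptive random-walk Metropolis block.

    ``on_set`` (if given) refreshes caches that depend on the block's
    parameters; it runs after every assignment, including the restore on
    rejection, so cached offsets always match the current state.
    """

    def __init__(self, name, get, set_, local_logpost, scale=0.1, on_set=None):
        self.name = name
        self.get = get
        self.set = set_
        self.on_set = on_set
        self.local_logpost = local_logpost
        self.log_scale = math.log(scale)
        self.n_prop = 0
        self.n_acc = 0

    def _assign(self, v):
        self.set(v)
        if self.on_set is not None:
            self.on_set()

    def step(self, rng, adapt: bool):
        cur = np.atleast_1d(self.get()).astype(float)
        cur_lp = self.local_logpost()
        prop = cur + math.exp(self.log_scale) * rng.standard_normal(cur.size)
        self._assign(prop)
        new_lp = self.local_logpost()
        self.n_prop += 1
        accept = np.isfinite(new_lp) and math.log(rng.random()) < new_lp - cur_lp
        if accept:
            self.n_acc += 1
        else:
            self._assign(cur)
        if adapt:
            step = (1.0 if accept else 0.0) - _TARGET_ACCEPT
            self.log_scale += step / max(1.0, self.n_prop ** 0.6) * 2.0
            self.log_scale = min(max(self.log_scale, -12.0), 4.0)

    @property
    def accept_rate(self) -> float:
        return self.n_acc / max(1, self.n_prop)


class _Sampler:
    def __init__(self, data: ModelData, fix: FixSpec, rng: np.random.Generator,
                 init_jitter: float = 0.0):
        self.data = data
        self.cfg = data.config
        self.fix = fix
        self.rng = rng
        self.avail_prior = beta_from_mean_cv(
            self.cfg.availability_mean, self.cfg.availability_cv)
        self.g0_prior = beta_from_mean_cv(
            self.cfg.g0_aerial_mean, self.cfg.g0_aerial_cv)
        self.state = self._initial_state(init_jitter)
        # cached pieces of the augmented CPG likelihood (the sampler maintains
        # the invariant G_i > 0 iff Y_i > 0, so validity checks live only in
        # the public likelihood functions)
        self.pos = data.Y > 0
        self.has_ship_cells = bool(np.any(data.ship_mask))
        self.has_aer_cells = bool(np.any(data.aer_mask))
        self.y_pos = data.Y[self.pos]
        self.log_y_pos = np.log(self.y_pos) if self.y_pos.size else self.y_pos
        self._g_version = 0
        self._sync_G_cache()
        self._ga_key = None
        self._ga_val = None
        self._p_cell = None
        self._refresh_offsets()
        self.blocks = self._build_blocks()

    def _sync_G_cache(self):
        self._g_pos = self.state.G[self.pos].astype(float)
        self._lgG1 = gammaln(self._g_pos + 1.0)
        self._g_version += 1

    # -- initialization -----------------------------------------------------
    def _init_detection(self, platform: str) -> DetectionParams:
        cfg = self.cfg
        key = cfg.key_ship if platform == "ship" else cfg.key_aerial
        arr = self.data.ship_sights if platform == "ship" else self.data.aer_sights
        k = len(self.data.det_cov_names)
        fixed_name = f"detection_{platform}"
        if self.fix.frozen(fixed_name):
            return self.fix.values[fixed_name]
        template = DetectionParams(
            key=key, log_sigma_coefs=np.zeros(1 + k), log_b=np.log(2.0),
            mr_coefs=np.concatenate([[1.0, -0.5], np.zeros(k)]),
            g0_source="mr" if platform == "ship" else "external",
            g0_external=1.0 if platform == "ship" else self.cfg.g0_aerial_mean)
        W = cfg.truncation[platform]
        template.log_sigma_coefs[0] = np.log(
            max(np.std(arr.y), 0.2 * W)) if arr.n else np.log(0.5 * W)
        if arr.n >= 10:
            cache = getattr(self.data, "_ml_cache", None)
            if cache is None:
                cache = self.data._ml_cache = {}
            if platform not in cache:
                try:
                    ml, _, _ = det_mod.fit_mrds_ml(
                        arr, key=key, W=W,
                        configuration="independent" if platform == "ship" else "trial",
                        include_capture=(platform == "ship"))
                    cache[platform] = ml
                except (RuntimeError, ValueError):
                    cache[platform] = None
            ml = cache[platform]
            if ml is not None:
                template = replace(template, log_sigma_coefs=ml.log_sigma_coefs,
                                   log_b=ml.log_b, mr_coefs=ml.mr_coefs)
        return template

    def _initial_state(self, jitter: float) -> ModelState:
        data, cfg, fix = self.data, self.cfg, self.fix
        det_ship = self._init_detection("ship")
        det_aer = self._init_detection("aerial")
        avail = (fix.values["availability"] if fix.frozen("availability")
                 else cfg.availability_mean)
        g0a = (det_aer.g0_external if fix.frozen("detection_aerial")
               else cfg.g0_aerial_mean)
        lam_s = (fix.values["lambda_s"] if fix.frozen("lambda_s")
                 else (float(np.mean(data.sizes) - 1.0) if data.sizes.size else
                       gs_mod.ZTP_PRIOR[0] / gs_mod.ZTP_PRIOR[1]))
        lam_s = max(lam_s, 1e-4)
        beta = np.zeros(data.n_coef)
        state = ModelState(
            beta=beta, phi=np.zeros(data.n_coef), log_alpha=0.0,
            gammas=np.full(2 * len(data.design.bases), 10.0),
            lambda_s=lam_s, det_ship=det_ship, det_aerial=det_aer,
            availability=avail, g0_aerial=g0a,
            G=np.ceil(data.Y).astype(np.int64))
        if data.n_cells:
            # ridge fit of log empirical rates: a non-degenerate starting
            # smooth keeps the first Gibbs draw of gamma at a realistic
            # scale (starting from beta = 0 would send gamma to ~a0/b0+rank
            # over b0 and over-shrink the smooth for many sweeps)
            p = _cell_detect_p(state, data)
            z = np.log((data.Y + 0.5) / np.maximum(p * data.A, 1e-12))
            X = data.design.X
            ridge = 0.1 * np.eye(X.shape[1])
            ridge[0, 0] = 1e-8
            state.beta = np.linalg.solve(X.T @ X + ridge, X.T @ z)
        if jitter > 0:
            state.beta = state.beta + self.rng.normal(scale=jitter, size=beta.size)
            state.log_alpha += self.rng.normal(scale=jitter)
        return state

    # -- cached offsets -----------------------------------------------------
    def _refresh_offsets(self, platform: str | None = None):
        data, st = self.data, self.state
        if not data.n_cells:
            self.log_off = np.zeros(0)
            return
        if platform is None or self._p_cell is None:
            self._p_cell = _cell_detect_p(st, data)
        else:
            mask = data.ship_mask if platform == "ship" else data.aer_mask
            if np.any(mask):
                params = st.det_ship if platform == "ship" else st.det_aerial
                z = data.Zdet[mask] if data.Zdet.shape[1] else None
                th = np.atleast_1d(det_mod.theta(z, params, data.W[mask]))
                a = 1.0 if platform == "ship" else st.availability
                self._p_cell[mask] = np.clip(th, 1e-300, 1.0) * a
        self.log_off = np.log(self._p_cell * data.A)

    # -- local log-posteriors ----------------------------------------------
    def _cpg_ll(self) -> float:
        data, st = self.data, self.state
        if not data.n_cells:
            return 0.0
        lp, lg = _cpg_lambdas(st, data, self.log_off)
        if lp is None:
            return -np.inf
        alpha = math.exp(st.log_alpha)
        ll = -float(np.sum(lp[~self.pos]))
        g = self._g_pos
        if g.size:
            lpp, lgp = lp[self.pos], lg[self.pos]
            ga = g * alpha
            key = (st.log_alpha, self._g_version)
            if self._ga_key != key:
                self._ga_val = gammaln(ga)
                self._ga_key = key
            rate = alpha / lgp
            ll += float(np.sum(
                g * np.log(lpp) - lpp - self._lgG1
                + ga * np.log(rate) - self._ga_val
                + (ga - 1.0) * self.log_y_pos - rate * self.y_pos))
        return ll

    def _smooth_prior_term(self, j: int) -> float:
        st, design = self.state, self.data.design
        basis, sl = design.bases[j], design.slices[j]
        g = sm_mod.SmoothingParams(st.gammas[2 * j: 2 * j + 2])
        return sm_mod.smooth_prior_logpdf(st.beta[sl], basis, g)

    def _lp_beta_block(self, j: int | None) -> float:
        prior = (_normal_logpdf(self.state.beta[0]) if j is None
                 else self._smooth_prior_term(j))
        return self._cpg_ll() + prior

    def _lp_phi(self) -> float:
        return self._cpg_ll() + _normal_logpdf(self.state.phi)

    def _lp_alpha(self) -> float:
        if self.state.log_alpha > math.log(ALPHA_MAX):
            return -np.inf
        return self._cpg_ll() + _normal_logpdf(self.state.log_alpha)

    def _lp_det_ship(self) -> float:
        st, cfg = self.state, self.cfg
        ll = det_mod.detection_loglik(self.data.ship_sights, st.det_ship,
                                      cfg.truncation["ship"], "independent")
        prior = (_normal_logpdf(st.det_ship.log_sigma_coefs)
                 + _normal_logpdf(st.det_ship.mr_coefs))
        if st.det_ship.key == "hazard_rate":
            prior += _normal_logpdf(st.det_ship.log_b)
        cpg = self._cpg_ll() if self.has_ship_cells else 0.0
        return ll + prior + cpg

    def _lp_det_aerial(self) -> float:
        st, cfg = self.state, self.cfg
        ll = det_mod.detection_loglik(self.data.aer_sights, st.det_aerial,
                                      cfg.truncation["aerial"], "trial",
                                      include_capture=False)
        prior = _normal_logpdf(st.det_aerial.log_sigma_coefs)
        if st.det_aerial.key == "hazard_rate":
            prior += _normal_logpdf(st.det_aerial.log_b)
        cpg = self._cpg_ll() if self.has_aer_cells else 0.0
        return ll + prior + cpg

    def _lp_logit_avail(self) -> float:
        a = self.state.availability
        cpg = self._cpg_ll() if self.has_aer_cells else 0.0
        # beta prior on the natural scale plus the logit-transform Jacobian
        return float(self.avail_prior.logpdf(a)) + math.log(a * (1 - a)) + cpg

    def _lp_logit_g0(self) -> float:
        g = self.state.g0_aerial
        cpg = self._cpg_ll() if self.has_aer_cells else 0.0
        return float(self.g0_prior.logpdf(g)) + math.log(g * (1 - g)) + cpg

    # -- block construction -------------------------------------------------
    def _build_blocks(self) -> list:
        st, data, fix = self.state, self.data, self.fix
        blocks = []
        if data.n_cells:
            def get_b0():
                return self.state.beta[0]

            def set_b0(v):
                self.state.beta[0] = _scalar(v)
            blocks.append(_Block("B0", get_b0, set_b0,
                                 lambda: self._lp_beta_block(None), scale=0.05))
            for j, sl in enumerate(data.design.slices):
                def get_s(sl=sl):
                    return self.state.beta[sl]

                def set_s(v, sl=sl):
                    self.state.beta[sl] = v
                blocks.append(_Block(f"beta_s{j}", get_s, set_s,
                                     lambda j=j: self._lp_beta_block(j),
                                     scale=0.1))
            if self.cfg.phi_mode == "intercept":
                def get_phi():
                    return self.state.phi[0]

                def set_phi(v):
                    self.state.phi[0] = _scalar(v)
                blocks.append(_Block("phi0", get_phi, set_phi, self._lp_phi,
                                     scale=0.1))
            else:
                def get_phiv():
                    return self.state.phi

                def set_phiv(v):
                    self.state.phi = np.atleast_1d(v)
                blocks.append(_Block("phi", get_phiv, set_phiv, self._lp_phi,
                                     scale=0.05))

            def get_la():
                return self.state.log_alpha

            def set_la(v):
                self.state.log_alpha = _scalar(v)
            blocks.append(_Block("log_alpha", get_la, set_la, self._lp_alpha,
                                 scale=0.2))

        if not fix.frozen("detection_ship"):
            def get_ds():
                p = self.state.det_ship
                v = [p.log_sigma_coefs]
                if p.key == "hazard_rate":
                    v.append([p.log_b])
                v.append(p.mr_coefs)
                return np.concatenate(v)

            def set_ds(v):
                p = self.state.det_ship
                ks = p.log_sigma_coefs.size
                i = ks
                v = np.atleast_1d(np.asarray(v, dtype=float))
                log_b = p.log_b
                if p.key == "hazard_rate":
                    log_b = float(v[ks])
                    i += 1
                self.state.det_ship = replace(
                    p, log_sigma_coefs=v[:ks].copy(), log_b=log_b,
                    mr_coefs=v[i:].copy())
            blocks.append(_Block("det_ship", get_ds, set_ds,
                                 self._lp_det_ship, scale=0.05,
                                 on_set=lambda: self._refresh_offsets("ship")))
        if not fix.frozen("detection_aerial"):
            def get_da():
                p = self.state.det_aerial
                v = [p.log_sigma_coefs]
                if p.key == "hazard_rate":
                    v.append([p.log_b])
                return np.concatenate(v)

            def set_da(v):
                p = self.state.det_aerial
                v = np.atleast_1d(np.asarray(v, dtype=float))
                ks = p.log_sigma_coefs.size
                log_b = float(v[ks]) if p.key == "hazard_rate" else p.log_b
                self.state.det_aerial = replace(
                    p, log_sigma_coefs=v[:ks].copy(), log_b=log_b)
            blocks.append(_Block("det_aerial", get_da, set_da,
                                 self._lp_det_aerial, scale=0.05,
                                 on_set=lambda: self._refresh_offsets("aerial")))

            def get_g0():
                return logit(self.state.g0_aerial)

            def set_g0(v):
                self.state.g0_aerial = float(expit(_scalar(v)))
            blocks.append(_Block("logit_g0_aerial", get_g0, set_g0,
                                 self._lp_logit_g0, scale=0.3,
                                 on_set=lambda: self._refresh_offsets("aerial")))
        if not fix.frozen("availability"):
            def get_a():
                return logit(self.state.availability)

            def set_a(v):
                self.state.availability = float(expit(_scalar(v)))
            blocks.append(_Block("logit_a", get_a, set_a,
                                 self._lp_logit_avail, scale=0.3,
                                 on_set=lambda: self._refresh_offsets("aerial")))
        return blocks

    # -- one sweep ----------------------------------------------------------
    def sweep(self, adapt: bool):
        st, data, rng = self.state, self.data, self.rng
        # exact conditional draws
        if data.n_cells:
            lp, lg = _cpg_lambdas(st, data, self.log_off)
            if lp is not None:
                st.G = cpg_mod.sample_latent_G_vec(
                    data.Y, lp, lg, math.exp(st.log_alpha), rng)
                self._sync_G_cache()
            for j in range(len(data.design.bases)):
                sl = data.design.slices[j]
                g = sm_mod.gibbs_update_gamma(
                    st.beta[sl], data.design.bases[j], rng=rng)
                st.gammas[2 * j: 2 * j + 2] = g.gamma_k
        if not self.fix.frozen("lambda_s"):
            st.lambda_s = gs_mod.gibbs_update_lambda_s(data.sizes, rng=rng)
        for b in self.blocks:
            b.step(rng, adapt)

    # -- recording ----------------------------------------------------------
    def record_names(self) -> list:
        names = []
        data, fix = self.data, self.fix
        if data.n_cells:
            names.append("B0")
            for j, (basis, sl) in enumerate(zip(data.design.bases, data.design.slices)):
                cov = basis.spec.covariate_name
                names += [f"s({cov}).{k}" for k in range(sl.stop - sl.start)]
            names += (["phi0"] if self.cfg.phi_mode == "intercept"
                      else [f"phi.{k}" for k in range(data.n_coef)])
            names.append("log_alpha")
            for j, basis in enumerate(data.design.bases):
                cov = basis.spec.covariate_name
                names += [f"gamma({cov})", f"gamma0({cov})"]
        if not fix.frozen("lambda_s"):
            names.append("lambda_s")
        if not fix.frozen("detection_ship"):
            p = self.state.det_ship
            names += [f"ship.log_sigma.{k}" for k in range(p.log_sigma_coefs.size)]
            if p.key == "hazard_rate":
                names.append("ship.log_b")
            names += [f"ship.delta.{k}" for k in range(p.mr_coefs.size)]
        if not fix.frozen("detection_aerial"):
            p = self.state.det_aerial
            names += [f"aerial.log_sigma.{k}" for k in range(p.log_sigma_coefs.size)]
            if p.key == "hazard_rate":
                names.append("aerial.log_b")
            names.append("g0_aerial")
        if not fix.frozen("availability"):
            names.append("availability")
        return names

    def record(self) -> np.ndarray:
        st, data, fix = self.state, self.data, self.fix
        out = []
        if data.n_cells:
            out.append(st.beta)
            out.append([st.phi[0]] if self.cfg.phi_mode == "intercept" else st.phi)
            out.append([st.log_alpha])
            out.append(st.gammas)
        if not fix.frozen("lambda_s"):
            out.append([st.lambda_s])
        if not fix.frozen("detection_ship"):
            p = st.det_ship
            out.append(p.log_sigma_coefs)
            if p.key == "hazard_rate":
                out.append([p.log_b])
            out.append(p.mr_coefs)
        if not fix.frozen("detection_aerial"):
            p = st.det_aerial
            out.append(p.log_sigma_coefs)
            if p.key == "hazard_rate":
                out.append([p.log_b])
            out.append([st.g0_aerial])
        if not fix.frozen("availability"):
            out.append([st.availability])
        return np.concatenate([np.atleast_1d(np.asarray(x, dtype=float))
                               for x in out])


def run_mcmc(cells, sightings, config: StudyConfig,
             fix: FixSpec | None = None, seed: int | None = None) -> PosteriorDraws:
    """Run the blockwise MCMC sampler and return retained draws.

    Retains ``n_chains * (n_iter - n_burn) / thin`` draws; fully reproducible
    given (seed, config).  Initialization uses stand-alone ML detection fits
    where enough sightings exist, with up to 100 jittered restarts if the
    initial state has non-finite posterior density.
    """
    fix = fix or FixSpec.none()
    seed = config.seed if seed is None else seed
    data = ModelData(cells, sightings, config)
    n_keep = (config.n_iter - config.n_burn) // config.thin

    chains_values = None
    names = None
    accept = {}
    for chain in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        sampler = None
        for attempt in range(101):
            cand = _Sampler(data, fix, rng, init_jitter=0.0 if attempt == 0 else 0.3)
            if np.isfinite(joint_logpost(cand.state, data, fix)):
                sampler = cand
                break
        if sampler is None:
            raise RuntimeError("no finite starting point found after 100 jittered restarts")
        if names is None:
            names = sampler.record_names()
            chains_values = np.empty((config.n_chains, n_keep, len(names)))
        kept = 0
        for it in range(config.n_iter):
            sampler.sweep(adapt=it < config.n_burn)
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0 \
                    and kept < n_keep:
                chains_values[chain, kept] = sampler.record()
                kept += 1
        accept[chain] = {b.name: b.accept_rate for b in sampler.blocks}

    values = {nm: chains_values[:, :, i] for i, nm in enumerate(names)}
    meta = {
        "n_chains": config.n_chains, "n_iter": config.n_iter,
        "n_burn": config.n_burn, "thin": config.thin, "seed": seed,
        "design": data.design, "fix": fix, "accept": accept,
        "phi_mode": config.phi_mode,
    }
    return PosteriorDraws(names=names, values=values, meta=meta)


# ---------------------------------------------------------------------------
# diagnostics and summaries

def gelman_rubin(draws: PosteriorDraws, parameter: str) -> float:
    """Split-chain potential scale reduction factor R-hat.

    Each chain is split in half (m half-chains of length n); with B the
    between-half-chain variance of means and W the mean within-half-chain
    variance, R-hat = sqrt(((n - 1)/n + B/(n W)) ) where B is on the
    per-observation scale (var of means times n).
    """
    x = draws.get(parameter)
    if x.shape[0] < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    if x.shape[1] < 20:
        raise ValueError("need at least 10 retained draws per half-chain")
    half = x.shape[1] // 2
    halves = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    n = halves.shape[1]
    means = halves.mean(axis=1)
    W = float(np.mean(halves.var(axis=1, ddof=1)))
    B_over_n = float(np.var(means, ddof=1))
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float).reshape(-1)
    n = x.size
    if n < 4:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    if acov[0] == 0:
        return float(n)
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n - 2, 2):
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def posterior_summary(draws, parameter=None, require_cv: bool = False) -> dict:
    """Mean, sd, CV and central 95% interval of pooled post-burn-in draws.

    The CV is sd/mean and needs a positive mean: for sign-changing or
    non-positive quantities it is NaN, or a ValueError if ``require_cv``.
    """
    if parameter is None:
        x = np.asarray(draws, dtype=float).reshape(-1)
    elif isinstance(parameter, str):
        x = draws.pooled(parameter)
    else:
        x = np.asarray(parameter, dtype=float).reshape(-1)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    sign_changing = x.size > 0 and (x.min() < 0.0 < x.max())
    if sd > 0 and (mean <= 0 or sign_changing):
        if require_cv:
            raise ValueError("CV undefined for a sign-changing or non-positive quantity")
        cv = np.nan
    else:
        cv = 0.0 if sd == 0 else sd / mean
    lo, hi = (np.quantile(x, [0.025, 0.975]) if x.size > 1 else (x[0], x[0]))
    return {"mean": mean, "sd": sd, "cv": float(cv),
            "q2.5": float(lo), "q97.5": float(hi)}
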