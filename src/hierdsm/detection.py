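"""Detection functions for double-observer (mark-recapture) distance sampling.

Implements the point-independence estimator: surface detectability within the
searched strip combines a conventional distance-sampling key function
``g(y, z)`` (half-normal or hazard-rate, with a log-linear scale model) with a
trackline detection probability ``g(0, z)`` estimated from two-observer
capture histories through a logistic conditional-detection model,

    theta(z) = g(0, z) * int_0^W g(y, z) dy / W.

Shipboard platforms contribute both a distance term and a capture-history
term to the likelihood; platforms whose trackline probability was estimated
externally (the aerial trial configuration) carry it as a parameter with an
informative beta prior instead.  Availability-at-the-surface ``a`` multiplies
the aerial detection probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import erf, expit, gammaln

__all__ = [
    "DetectionParams", "BetaPrior", "SightingArrays",
    "key_prob", "esw", "trackline_prob", "theta", "effective_p",
    "beta_from_mean_cv", "detection_loglik", "fit_mrds_ml",
]

_SQRT2 = np.sqrt(2.0)
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)
_GL_NODES_2X, _GL_WEIGHTS_2X = np.polynomial.legendre.leggauss(128)

# Cap on alpha+beta of a moment-matched beta prior; beyond this the prior is
# numerically degenerate (CV ~ 0) and should be replaced by fixing the value.
_BETA_CONCENTRATION_CAP = 1e8


@dataclass
class DetectionParams:
    """Parameters of the per-platform detection model.

    ``log_sigma_coefs`` is the log-linear scale model (intercept first), so
    sigma(z) = exp(c0 + z @ c[1:]).  ``mr_coefs`` is the logistic
    conditional-detection model (intercept, perpendicular-distance slope,
    then covariates).  ``g0_source`` selects whether the trackline
    probability comes from the mark-recapture model ("mr") or from the
    externally estimated ``g0_external`` (the aerial trial configuration).
    """

    key: str = "half_normal"
    log_sigma_coefs: np.ndarray = field(default_factory=lambda: np.zeros(1))
    log_b: float = 0.0
    mr_coefs: np.ndarray = field(default_factory=lambda: np.zeros(2))
    g0_source: str = "mr"
    g0_external: float = 1.0
    availability: float = 1.0

    def __post_init__(self) -> None:
        if self.key not in ("half_normal", "hazard_rate"):
            raise ValueError(f"unknown key function {self.key!r}")
        self.log_sigma_coefs = np.atleast_1d(np.asarray(self.log_sigma_coefs, dtype=float))
        self.mr_coefs = np.atleast_1d(np.asarray(self.mr_coefs, dtype=float))
        if not (0.0 < self.g0_external <= 1.0):
            raise ValueError("g0_external must be in (0, 1]")
        if not (0.0 < self.availability <= 1.0):
            raise ValueError("availability must be in (0, 1]")

    def sigma(self, z: np.ndarray | None = None) -> np.ndarray:
        """Scale sigma(z) = exp(c0 + z @ c[1:]); z has one row per evaluation."""
        c = self.log_sigma_coefs
        if z is None or c.size == 1:
            eta = np.full(1 if z is None else np.atleast_2d(z).shape[0], c[0])
        else:
            z2 = np.atleast_2d(np.asarray(z, dtype=float))
            eta = c[0] + z2 @ c[1:]
        if not np.all(np.isfinite(eta)):
            raise ValueError("non-finite detection scale linear predictor")
        return np.exp(eta)

    @property
    def b(self) -> float:
        return float(np.exp(self.log_b))


@dataclass(frozen=True)
class BetaPrior:
    """Beta prior moment-matched to a (mean, CV) pair."""

    alpha: float
    beta: float
    source_mean: float
    source_cv: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def cv(self) -> float:
        s = self.alpha + self.beta
        var = self.alpha * self.beta / (s * s * (s + 1.0))
        return float(np.sqrt(var) / self.mean)

    def logpdf(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            out = (
                (self.alpha - 1.0) * np.log(x)
                + (self.beta - 1.0) * np.log1p(-x)
                + gammaln(self.alpha + self.beta)
                - gammaln(self.alpha)
                - gammaln(self.beta)
            )
        return out if out.ndim else float(out)


def beta_from_mean_cv(mean: float, cv: float) -> BetaPrior:
    """Moment-match a beta distribution to a mean and coefficient of variation.

    Solves alpha + beta = mean (1 - mean) / var - 1 with var = (mean cv)^2,
    then alpha = mean (alpha + beta).  Rejects variances too large for a
    beta on (0, 1) and degenerate near-point-mass priors.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError("mean must be in (0, 1)")
    if cv <= 0.0:
        raise ValueError("cv must be positive")
    var = (mean * cv) ** 2
    if var >= mean * (1.0 - mean):
        raise ValueError(f"variance {var:.4g} too large for a beta with mean {mean}")
    conc = mean * (1.0 - mean) / var - 1.0
    if conc > _BETA_CONCENTRATION_CAP:
        raise ValueError("prior is numerically degenerate (alpha+beta > 1e8); fix the value instead")
    return BetaPrior(alpha=mean * conc, beta=(1.0 - mean) * conc, source_mean=mean, source_cv=cv)


def key_prob(y, z, params: DetectionParams):
    """Detection-function value g(y, z) at perpendicular distance y (km).

    half-normal: exp(-y^2 / (2 sigma(z)^2));
    hazard-rate: 1 - exp(-(y / sigma(z))^(-b)), with g(0) = 1 by the
    continuous limit.  Non-increasing in y, in (0, 1].
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("perpendicular distance must be >= 0")
    sigma = params.sigma(z)
    sigma = np.broadcast_to(sigma, y.shape) if y.ndim else sigma[0]
    if params.key == "half_normal":
        out = np.exp(-0.5 * (y / sigma) ** 2)
    else:
        b = params.b
        with np.errstate(divide="ignore", over="ignore"):
            out = -np.expm1(-np.where(y > 0, y / sigma, np.inf) ** (-b))
        out = np.where(y > 0, out, 1.0)
    return out if np.ndim(out) else float(out)


def _esw_quadrature(params: DetectionParams, z, W) -> np.ndarray:
    W = np.atleast_1d(np.asarray(W, dtype=float))
    half = 0.5 * W
    res = []
    for nodes, weights in ((_GL_NODES, _GL_WEIGHTS), (_GL_NODES_2X, _GL_WEIGHTS_2X)):
        y = half[:, None] * (nodes[None, :] + 1.0)  # map [-1,1] -> [0,W]
        sig = params.sigma(z)
        sig = np.broadcast_to(np.atleast_1d(sig), W.shape)
        if params.key == "half_normal":
            g = np.exp(-0.5 * (y / sig[:, None]) ** 2)
        else:
            g = -np.expm1(-(y / sig[:, None]) ** (-params.b))
        res.append(half * (g @ weights))
    lo, hi = res
    rel = np.abs(hi - lo) / np.maximum(np.abs(hi), 1e-300)
    if np.any(rel > 1e-8):
        raise RuntimeError("effective strip width quadrature did not converge on node doubling")
    return hi


def esw(params: DetectionParams, z, W, *, force_quadrature: bool = False):
    """Effective half-strip width int_0^W g(y, z) dy in km.

    Half-normal analytically via the Gaussian error function,
    sigma sqrt(pi/2) erf(W / (sigma sqrt 2)); hazard-rate by 64-node
    Gauss-Legendre quadrature with a node-doubling convergence check.
    """
    W_arr = np.atleast_1d(np.asarray(W, dtype=float))
    if np.any(W_arr <= 0):
        raise ValueError("truncation distance W must be positive")
    if params.key == "half_normal" and not force_quadrature:
        sigma = np.broadcast_to(np.atleast_1d(params.sigma(z)), W_arr.shape)
        out = sigma * np.sqrt(np.pi / 2.0) * erf(W_arr / (sigma * _SQRT2))
    else:
        out = _esw_quadrature(params, z, W_arr)
    return out if np.ndim(W) else float(out[0])


def trackline_prob(z, y, params: DetectionParams, configuration: str = "independent"):
    """Platform detection probability from the conditional-observer logistic.

    The conditional probability that one observer detects a group present at
    distance y is p(y, z) = logistic(d0 + d_y y + z @ d[2:]).  With two
    observers scored independently at the trackline ("independent"
    configuration, a two-way removal) the platform probability is
    1 - (1 - p)^2; in the "trial" configuration (one team generates trials
    for the other) it is p itself.
    """
    p = _cond_obs_prob(z, y, params)
    if configuration == "independent":
        out = 1.0 - (1.0 - p) ** 2
    elif configuration == "trial":
        out = p
    else:
        raise ValueError(f"unknown configuration {configuration!r}")
    return out if np.ndim(out) else float(out)


def _cond_obs_prob(z, y, params: DetectionParams):
    d = params.mr_coefs
    y = np.asarray(y, dtype=float)
    eta = d[0] + d[1] * y
    if d.size > 2:
        z2 = np.atleast_2d(np.asarray(z, dtype=float))
        eta = eta + np.squeeze(z2 @ d[2:]) if z2.size else eta
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite mark-recapture linear predictor")
    return expit(eta)


def g0(z, params: DetectionParams, configuration: str = "independent"):
    """Trackline probability g(0, z): mark-recapture model or external estimate."""
    if params.g0_source == "external":
        zz = np.atleast_2d(np.asarray(z, dtype=float)) if z is not None else np.zeros((1, 0))
        out = np.full(zz.shape[0], params.g0_external)
        return out if np.ndim(z) and np.asarray(z).ndim > 1 else float(out[0])
    return trackline_prob(z, 0.0, params, configuration)


def theta(z, params: DetectionParams, W, configuration: str = "independent"):
    """Point-independence detection probability g(0, z) * esw(z, W) / W."""
    return g0(z, params, configuration) * esw(params, z, W) / W


def effective_p(platform: str, theta_val, a):
    """Survey-specific detection probability: ship p = theta; aerial p = theta * a."""
    theta_arr = np.asarray(theta_val, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(theta_arr <= 0) or np.any(theta_arr > 1) or np.any(a <= 0) or np.any(a > 1):
        raise ValueError("theta and availability must lie in (0, 1]")
    if platform == "ship":
        out = theta_arr
    elif platform == "aerial":
        out = theta_arr * a
    else:
        raise ValueError(f"unknown platform {platform!r}")
    return out if np.ndim(theta_val) else float(out)


@dataclass
class SightingArrays:
    """Column-array view of a sighting table, the unit the likelihood consumes."""

    y: np.ndarray                 # perpendicular distance, km
    omega: np.ndarray             # (n, 2) capture-history indicators
    scale_covs: np.ndarray        # (n, k_s) covariates of the scale model
    mr_covs: np.ndarray           # (n, k_m) covariates of the MR logistic

    @classmethod
    def from_records(cls, sightings: Iterable, scale_cov_names: Sequence[str] = (),
                     mr_cov_names: Sequence[str] = ()) -> "SightingArrays":
        recs = list(sightings)
        n = len(recs)
        y = np.array([r.distance_km for r in recs], dtype=float)
        omega = np.array([r.capture for r in recs], dtype=int).reshape(n, 2)
        sc = np.array([[r.detect_covs[c] for c in scale_cov_names] for r in recs],
                      dtype=float).reshape(n, len(scale_cov_names))
        mc = np.array([[r.detect_covs[c] for c in mr_cov_names] for r in recs],
                      dtype=float).reshape(n, len(mr_cov_names))
        return cls(y=y, omega=omega, scale_covs=sc, mr_covs=mc)

    @property
    def n(self) -> int:
        return self.y.size


def _as_arrays(sightings) -> SightingArrays:
    if isinstance(sightings, SightingArrays):
        return sightings
    return SightingArrays.from_records(sightings)


def capture_history_loglik(arr: SightingArrays, params: DetectionParams,
                           configuration: str = "independent") -> float:
    """Bernoulli log-likelihood of the two-observer capture histories.

    Independent configuration: conditional on detection by at least one
    observer, histories (1,1), (1,0), (0,1) have probabilities p^2/d,
    p(1-p)/d, p(1-p)/d with d = 1 - (1-p)^2, p evaluated at the sighting's
    distance.  Trial configuration: rows where the trial team detected
    (omega_2 = 1) score the other team's indicator as Bernoulli(p).
    """
    p = _cond_obs_prob(arr.mr_covs, arr.y, params)
    p = np.clip(p, 1e-300, 1.0 - 1e-12)
    w1, w2 = arr.omega[:, 0], arr.omega[:, 1]
    if configuration == "independent":
        denom = 1.0 - (1.0 - p) ** 2
        ll = (w1 + w2) * np.log(p) + (2 - w1 - w2) * np.log1p(-p) - np.log(denom)
        return float(np.sum(ll))
    if configuration == "trial":
        trials = w2 == 1
        pt = p[trials]
        return float(np.sum(w1[trials] * np.log(pt) + (1 - w1[trials]) * np.log1p(-pt)))
    raise ValueError(f"unknown configuration {configuration!r}")


def distance_loglik(arr: SightingArrays, params: DetectionParams, W) -> float:
    """Conditional distance log-density sum_t log[g(y_t, z_t) / esw(z_t, W)]."""
    g = key_prob(arr.y, arr.scale_covs if arr.scale_covs.size else None, params)
    mu = esw(params, arr.scale_covs if arr.scale_covs.size else None,
             np.broadcast_to(np.asarray(W, dtype=float), arr.y.shape))
    g = np.atleast_1d(g)
    if np.any(g <= 0):
        return -np.inf
    return float(np.sum(np.log(g) - np.log(mu)))


def detection_loglik(sightings, params: DetectionParams, W,
                     configuration: str = "independent",
                     include_capture: bool = True) -> float:
    """Full detection log-likelihood: distance term plus capture-history term.

    Returns -inf (not an exception) for zero-probability configurations so
    that Metropolis proposals can be rejected cleanly.
    """
    arr = _as_arrays(sightings)
    if arr.n == 0:
        return 0.0
    ll = distance_loglik(arr, params, W)
    if include_capture and np.isfinite(ll):
        ll += capture_history_loglik(arr, params, configuration)
    return ll


# ---------------------------------------------------------------------------
# Stand-alone maximum-likelihood MRDS fit

def _pack(params: DetectionParams) -> np.ndarray:
    v = [params.log_sigma_coefs]
    if params.key == "hazard_rate":
        v.append([params.log_b])
    v.append(params.mr_coefs)
    return np.concatenate([np.atleast_1d(np.asarray(x, dtype=float)) for x in v])


def _unpack(vec: np.ndarray, template: DetectionParams) -> DetectionParams:
    ks = template.log_sigma_coefs.size
    i = ks
    log_b = template.log_b
    if template.key == "hazard_rate":
        log_b = float(vec[i])
        i += 1
    return replace(template, log_sigma_coefs=vec[:ks].copy(), log_b=log_b,
                   mr_coefs=vec[i:].copy())


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = x.size
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h * h)
    return H


def _numeric_grad(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.empty(x.size)
    for i in range(x.size):
        e = np.zeros(x.size); e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g


def fit_mrds_ml(sightings, key: str = "hazard_rate",
                configuration: str = "independent", W: float = 1.0,
                n_scale_covs: int | None = None, n_mr_covs: int | None = None,
                include_capture: bool = True, n_restarts: int = 4,
                seed: int = 0):
    """Stand-alone maximum-likelihood mark-recapture distance-sampling fit.

    Quasi-Newton (BFGS) maximization of :func:`detection_loglik` with jittered
    restarts; the covariance matrix is the inverse observed information from a
    central-difference Hessian.  Returns ``(params, cov, summary)`` where
    ``summary`` reports the mean distance-component probability
    (mean esw / W), mean g(0), and delta-method CVs.
    """
    arr = _as_arrays(sightings)
    if arr.n < 10:
        raise ValueError("need at least 10 sightings for a stand-alone fit")
    template = DetectionParams(
        key=key,
        log_sigma_coefs=np.zeros(1 + arr.scale_covs.shape[1]),
        log_b=np.log(2.0),
        mr_coefs=np.zeros(2 + arr.mr_covs.shape[1]),
    )
    x0 = _pack(template)
    x0[0] = np.log(max(np.std(arr.y), 0.2 * W))  # scale near data spread
    x0[template.log_sigma_coefs.size + (1 if key == "hazard_rate" else 0)] = 1.0

    def nll(x):
        p = _unpack(x, template)
        ll = detection_loglik(arr, p, W, configuration, include_capture)
        return -ll if np.isfinite(ll) else 1e12

    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        start = x0 if r == 0 else x0 + rng.normal(scale=0.5, size=x0.size)
        res = minimize(nll, start, method="BFGS",
                       options={"gtol": 1e-7, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("MRDS maximum-likelihood fit did not converge")

    xhat = best.x
    params = _unpack(xhat, template)
    H = _numeric_hessian(nll, xhat)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)

    def mean_pd(x):
        p = _unpack(x, template)
        z = arr.scale_covs if arr.scale_covs.size else None
        return float(np.mean(np.atleast_1d(esw(p, z, np.full(arr.n, W)))) / W)

    def mean_g0(x):
        p = _unpack(x, template)
        return float(np.mean(np.atleast_1d(
            trackline_prob(arr.mr_covs, 0.0, p, configuration))))

    def mean_theta(x):
        return mean_pd(x) * mean_g0(x)

    summary = {}
    for name, fn in (("mean_pd", mean_pd), ("mean_g0", mean_g0),
                     ("mean_theta", mean_theta)):
        val = fn(xhat)
        grad = _numeric_grad(fn, xhat)
        var = float(grad @ cov @ grad)
        summary[name] = val
        summary[f"{name}_cv"] = float(np.sqrt(max(var, 0.0)) / val)
    summary["loglik"] = -float(best.fun)
    return params, cov, summary
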