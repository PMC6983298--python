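"""Penalized regression-spline machinery for the density--habitat surface.

Each habitat covariate enters through a smooth f(x) = sum_k beta_k b_k(x)
with a quadratic roughness penalty gamma beta' S beta.  Identifiability with
the model intercept is obtained by absorbing the sum-to-zero constraint
(columns of the training design sum to zero) into a reparameterization, and
a rank-completing penalty on the nullspace of S (with its own smoothing
parameter) makes the implied multivariate-normal prior

    beta ~ MVN(0, precision = sum_k gamma_k S_k)

proper.  Smoothing parameters get conjugate Gamma(0.05, 0.005) priors
(shape-rate, prior mean 10) and are updated by Gibbs sampling.

Two basis families are provided: cubic regression splines (values-at-knots
parameterization with the exact integrated-squared-second-derivative
penalty; natural boundary conditions, hence linear extrapolation) and 1-D
thin-plate splines (radial basis r^3/12 on the constrained subspace plus a
linear term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, null_space

__all__ = [
    "SmoothSpec", "SmoothBasis", "SmoothingParams",
    "build_basis", "predict_basis", "smooth_prior_logpdf", "gibbs_update_gamma",
    "build_design",
]

_EIG_TOL = 1e-10
GAMMA_PRIOR = (0.05, 0.005)  # shape, rate


@dataclass(frozen=True)
class SmoothSpec:
    """Specification of one smooth term."""

    covariate_name: str
    basis_type: str = "cubic_regression"
    K: int = 5
    knot_rule: str = "quantile"

    def __post_init__(self):
        if self.K < 3:
            raise ValueError("basis size K must be >= 3")
        if self.basis_type not in ("cubic_regression", "thin_plate"):
            raise ValueError(f"unknown basis type {self.basis_type!r}")
        if self.knot_rule not in ("quantile", "even"):
            raise ValueError(f"unknown knot rule {self.knot_rule!r}")


@dataclass
class SmoothingParams:
    """Positive precision weights, one per penalty matrix (nullspace last)."""

    gamma_k: np.ndarray

    def __post_init__(self):
        self.gamma_k = np.atleast_1d(np.asarray(self.gamma_k, dtype=float))
        if np.any(self.gamma_k <= 0):
            raise ValueError("smoothing parameters must be positive")


@dataclass
class SmoothBasis:
    """Centered spline design with its penalty matrices and prediction state."""

    spec: SmoothSpec
    knots: np.ndarray
    design_columns: np.ndarray          # (n, K-1), columns sum to zero
    penalty_mats: list                  # [S_main] in constrained coordinates
    nullspace_penalty: np.ndarray       # rank-completing PSD matrix
    constraint_transform: np.ndarray    # (K, K-1) sum-to-zero reparameterization
    penalty_ranks: np.ndarray = field(default=None)
    _tp_Zc: np.ndarray = field(default=None, repr=False)

    @property
    def dim(self) -> int:
        return self.design_columns.shape[1]

    def all_penalties(self) -> list:
        return list(self.penalty_mats) + [self.nullspace_penalty]


# ---------------------------------------------------------------------------
# raw (unconstrained) bases

def _place_knots(x: np.ndarray, spec: SmoothSpec) -> np.ndarray:
    ux = np.unique(x)
    if ux.size < spec.K:
        raise ValueError(
            f"covariate {spec.covariate_name!r} has {ux.size} unique values; "
            f"reduce K below {spec.K}")
    if spec.knot_rule == "even":
        return np.linspace(ux[0], ux[-1], spec.K)
    knots = np.quantile(ux, np.linspace(0.0, 1.0, spec.K))
    # quantile ties would collapse intervals; nudge to strictly increasing
    for i in range(1, spec.K):
        if knots[i] <= knots[i - 1]:
            knots[i] = knots[i - 1] + 1e-8 * max(1.0, abs(knots[i - 1]))
    return knots


def _cr_matrices(knots: np.ndarray):
    """Penalty and curvature maps of the cubic regression spline.

    With beta the spline values at the K knots, the natural interpolating
    cubic has interior second derivatives F beta with F = B^{-1} D, and the
    integrated squared second derivative is beta' D' B^{-1} D beta.
    """
    K = knots.size
    h = np.diff(knots)
    D = np.zeros((K - 2, K))
    B = np.zeros((K - 2, K - 2))
    for i in range(K - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < K - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    Binv_D = np.linalg.solve(B, D)
    F_full = np.zeros((K, K))
    F_full[1:-1] = Binv_D
    S = D.T @ Binv_D
    S = 0.5 * (S + S.T)
    return S, F_full


def _cr_design(x: np.ndarray, knots: np.ndarray, F_full: np.ndarray) -> np.ndarray:
    K = knots.size
    h = np.diff(knots)
    x = np.asarray(x, dtype=float)
    X = np.zeros((x.size, K))
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, K - 2)
    xl, xr = knots[j], knots[j + 1]
    hj = h[j]
    am = (xr - x) / hj
    ap = (x - xl) / hj
    cm = ((xr - x) ** 3 / hj - hj * (xr - x)) / 6.0
    cp = ((x - xl) ** 3 / hj - hj * (x - xl)) / 6.0
    rows = np.arange(x.size)
    X[rows, j] += am
    X[rows, j + 1] += ap
    X += cm[:, None] * F_full[j] + cp[:, None] * F_full[j + 1]
    return X


def _tp_eta(r: np.ndarray) -> np.ndarray:
    return np.abs(r) ** 3 / 12.0


def _tp_matrices(knots: np.ndarray):
    K = knots.size
    E = _tp_eta(knots[:, None] - knots[None, :])
    T = np.column_stack([np.ones(K), knots])
    Zc = null_space(T.T)                      # (K, K-2)
    S_delta = Zc.T @ E @ Zc
    S_delta = 0.5 * (S_delta + S_delta.T)
    # raw coefficient order: (delta-tilde, a0, a1); penalty only on delta-tilde
    S = np.zeros((K, K))
    S[: K - 2, : K - 2] = S_delta
    return S, Zc


def _tp_design(x: np.ndarray, knots: np.ndarray, Zc: np.ndarray) -> np.ndarray:
    Phi = _tp_eta(np.asarray(x, dtype=float)[:, None] - knots[None, :])
    return np.column_stack([Phi @ Zc, np.ones(x.size), x])


def _raw_design(x: np.ndarray, basis: "SmoothBasis") -> np.ndarray:
    if basis.spec.basis_type == "cubic_regression":
        return _cr_design(x, basis.knots, basis._cr_F)
    return _tp_design(x, basis.knots, basis._tp_Zc)


# ---------------------------------------------------------------------------

def build_basis(x, spec: SmoothSpec) -> SmoothBasis:
    """Build the centered spline basis and its penalties at training values x."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < spec.K:
        raise ValueError("x must be a 1-D vector of length >= K")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate values must be finite")
    knots = _place_knots(x, spec)

    if spec.basis_type == "cubic_regression":
        S_raw, F_full = _cr_matrices(knots)
        X_raw = _cr_design(x, knots, F_full)
        tp_Zc = None
    else:
        S_raw, tp_Zc = _tp_matrices(knots)
        X_raw = _tp_design(x, knots, tp_Zc)
        F_full = None

    # absorb the sum-to-zero constraint: columns of X_raw @ Z sum to zero
    C = X_raw.sum(axis=0)
    Q, _ = np.linalg.qr(C[:, None], mode="complete")
    Z = Q[:, 1:]
    Xc = X_raw @ Z
    Sc = Z.T @ S_raw @ Z
    Sc = 0.5 * (Sc + Sc.T)

    evals, evecs = np.linalg.eigh(Sc)
    if np.min(evals) < -_EIG_TOL * max(1.0, np.max(np.abs(evals))):
        raise RuntimeError("penalty matrix is not positive semi-definite")
    tol = _EIG_TOL * max(1.0, np.max(np.abs(evals)))
    null_cols = evecs[:, evals <= tol]
    S_null = null_cols @ null_cols.T
    rank_main = int(np.sum(evals > tol))

    basis = SmoothBasis(
        spec=spec, knots=knots, design_columns=Xc,
        penalty_mats=[Sc], nullspace_penalty=S_null,
        constraint_transform=Z,
        penalty_ranks=np.array([rank_main, Xc.shape[1] - rank_main]),
        _tp_Zc=tp_Zc,
    )
    basis._cr_F = F_full
    return basis


def predict_basis(x_new, basis: SmoothBasis) -> np.ndarray:
    """Evaluate the constrained basis at new covariate values.

    Values beyond the knot range trigger a warning and are handled by linear
    extension of the smooth from the boundary (first-order Taylor expansion
    of each basis function at the nearest knot).
    """
    x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
    lo, hi = basis.knots[0], basis.knots[-1]
    outside = (x_new < lo) | (x_new > hi)
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} prediction values outside the knot range of "
            f"{basis.spec.covariate_name!r}; applying linear extension",
            stacklevel=2)
    x_eval = np.clip(x_new, lo, hi)
    X = _raw_design(x_eval, basis)
    if np.any(outside):
        h = 1e-6 * (hi - lo)
        for bound in (lo, hi):
            mask = (x_new < lo) if bound == lo else (x_new > hi)
            if not np.any(mask):
                continue
            xb = np.array([bound - h if bound == hi else bound,
                           bound if bound == hi else bound + h])
            rows = _raw_design(xb, basis)
            deriv = (rows[1] - rows[0]) / h
            X[mask] += (x_new[mask] - bound)[:, None] * deriv[None, :]
    return X @ basis.constraint_transform


def smooth_prior_logpdf(beta_s, basis: SmoothBasis, gammas: SmoothingParams) -> float:
    """Exact MVN log-density of the smooth coefficients under the penalty prior.

    The precision is sum_k gamma_k S_k including the rank-completing
    nullspace penalty; the normalizing constant uses its log-determinant.
    """
    beta_s = np.asarray(beta_s, dtype=float)
    mats = basis.all_penalties()
    g = gammas.gamma_k
    if g.size != len(mats):
        raise ValueError("one gamma per penalty matrix required")
    P = sum(gk * Sk for gk, Sk in zip(g, mats))
    try:
        c, low = cho_factor(P)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - nullspace penalty prevents this
        raise np.linalg.LinAlgError("singular smoothing precision") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = float(beta_s @ P @ beta_s)
    d = beta_s.size
    return 0.5 * logdet - 0.5 * d * np.log(2.0 * np.pi) - 0.5 * quad


def gibbs_update_gamma(beta_s, basis: SmoothBasis, prior=GAMMA_PRIOR,
                       rng: np.random.Generator | None = None) -> SmoothingParams:
    """Draw each smoothing parameter from its conjugate Gamma full conditional.

    gamma_k | beta ~ Gamma(a0 + rank(S_k)/2, b0 + beta' S_k beta / 2)
    in the shape-rate convention.
    """
    rng = np.random.default_rng() if rng is None else rng
    a0, b0 = prior
    beta_s = np.asarray(beta_s, dtype=float)
    out = []
    for Sk, rk in zip(basis.all_penalties(), basis.penalty_ranks):
        quad = float(beta_s @ Sk @ beta_s)
        if quad < -1e-8:
            raise ValueError("negative penalty quadratic form; penalty not PSD")
        quad = max(quad, 0.0)
        out.append(rng.gamma(shape=a0 + 0.5 * rk, scale=1.0 / (b0 + 0.5 * quad)))
    return SmoothingParams(np.array(out))


# ---------------------------------------------------------------------------
# multi-smooth design assembly used by the hierarchical model

@dataclass
class DesignInfo:
    """Intercept-plus-smooths design matrix with per-term bookkeeping."""

    X: np.ndarray                      # (n, 1 + sum_j (K_j - 1))
    bases: list                        # SmoothBasis per term
    slices: list                       # column slice per term (into X)

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    def predict(self, covariates: dict) -> np.ndarray:
        cols = [np.ones(len(next(iter(covariates.values()))))]
        for b, _ in zip(self.bases, self.slices):
            name = b.spec.covariate_name
            if name not in covariates:
                raise KeyError(f"prediction table is missing covariate {name!r}")
            cols.append(predict_basis(np.asarray(covariates[name], dtype=float), b))
        return np.column_stack(cols)


def build_design(covariates: dict, specs: Sequence[SmoothSpec]) -> DesignInfo:
    """Assemble [1 | smooth_1 | smooth_2 | ...] from named covariate vectors."""
    n = len(next(iter(covariates.values()))) if covariates else 0
    cols = [np.ones(n)]
    bases, slices = [], []
    start = 1
    for spec in specs:
        if spec.covariate_name not in covariates:
            raise KeyError(f"cell table is missing habitat covariate {spec.covariate_name!r}")
        b = build_basis(np.asarray(covariates[spec.covariate_name], dtype=float), spec)
        cols.append(b.design_columns)
        bases.append(b)
        slices.append(slice(start, start + b.dim))
        start += b.dim
    return DesignInfo(X=np.column_stack(cols), bases=bases, slices=slices)
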