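"""Shifted-Poisson model for observed group sizes.

Observed group sizes s_t >= 1 are modeled as (s_t - 1) ~ Poisson(lambda_s),
the "zero-truncated Poisson" of the abundance model, so lambda_s + 1 is the
mean group size.  Group size is assumed unrelated to detection probability,
so the model factorizes out of the detection likelihood and admits an exact
conjugate gamma update:

    lambda_s | s ~ Gamma(a0 + sum_t (s_t - 1), b0 + T)   (shape-rate).

The default prior Gamma(0.01, 0.01) is vague.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["GroupSizeParams", "ztp_loglik", "gibbs_update_lambda_s", "ZTP_PRIOR"]

ZTP_PRIOR = (0.01, 0.01)  # shape, rate


@dataclass(frozen=True)
class GroupSizeParams:
    lambda_s: float

    def __post_init__(self):
        if self.lambda_s < 0:
            raise ValueError("lambda_s must be nonnegative")

    @property
    def mean_group_size(self) -> float:
        return self.lambda_s + 1.0


def ztp_loglik(sizes, lambda_s: float) -> float:
    """Log-likelihood sum_t log Poisson(s_t - 1; lambda_s)."""
    s = np.asarray(sizes)
    if np.any(s < 1):
        raise ValueError("group sizes must be >= 1")
    if lambda_s < 0:
        raise ValueError("lambda_s must be nonnegative")
    k = s.astype(float) - 1.0
    if lambda_s == 0:
        return 0.0 if np.all(k == 0) else -np.inf
    return float(np.sum(k * np.log(lambda_s) - lambda_s - gammaln(k + 1.0)))


def gibbs_update_lambda_s(sizes, prior=ZTP_PRIOR,
                          rng: np.random.Generator | None = None) -> float:
    """Draw lambda_s from its conjugate Gamma full conditional."""
    rng = np.random.default_rng() if rng is None else rng
    a0, b0 = prior
    s = np.asarray(sizes)
    if s.size and np.any(s < 1):
        raise ValueError("group sizes must be >= 1")
    shape = a0 + float(np.sum(s - 1)) if s.size else a0
    rate = b0 + s.size
    return float(rng.gamma(shape=shape, scale=1.0 / rate))
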