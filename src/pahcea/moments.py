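"""Method-of-moments distribution fitting and sampling.

Every uncertain model input is reported as a mean and a standard error
together with a distribution family, the convention of probabilistic
decision models: probabilities and utilities are beta, costs and counts
are gamma, and relative risks (ratio parameters, support (0, inf)) are
lognormal. Each fit matches the first two moments exactly, so the base
case (evaluated at the means) is unchanged by the family choice; the
family shapes only the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, model_validator

Family = Literal["beta", "gamma", "lognormal", "fixed"]


class InfeasibleMomentsError(ValueError):
    """Raised when (mean, se) cannot be matched by the requested family."""


class MomentSpec(BaseModel):
    """A model input summarised by its mean, standard error and family.

    ``se`` is the standard error of the mean estimate, in the same units
    as the mean; ``family='fixed'`` marks quantities carried without
    uncertainty (their ``se`` is coerced to zero).
    """

    mean: float
    se: float = 0.0
    family: Family = "fixed"

    @model_validator(mode="after")
    def _check(self) -> "MomentSpec":
        if self.se < 0:
            raise ValueError(f"se must be >= 0, got {self.se}")
        if self.family == "beta" and not (0.0 <= self.mean <= 1.0):
            raise ValueError(f"beta mean must lie in [0, 1], got {self.mean}")
        if self.family == "fixed" and self.se != 0.0:
            object.__setattr__(self, "se", 0.0)
        return self

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the fitted distribution (degenerate when se == 0)."""
        return sample_from_moments(self.mean, self.se, self.family, rng, size=size, name="")

    def fitted_params(self) -> tuple[float, float]:
        if self.family == "beta":
            return fit_beta_from_moments(self.mean, self.se)
        if self.family == "gamma":
            return fit_gamma_from_moments(self.mean, self.se)
        if self.family == "lognormal":
            return fit_lognormal_from_moments(self.mean, self.se)
        raise ValueError("fixed quantities have no fitted distribution")


def fit_beta_from_moments(mean: float, se: float, name: str = "") -> tuple[float, float]:
    """Beta(alpha, beta) shape pair matching ``mean`` and variance ``se**2``.

    Uses alpha = mean*k, beta = (1-mean)*k with k = mean(1-mean)/se^2 - 1;
    feasible only when 0 < se^2 < mean(1-mean).
    """
    label = f" for {name!r}" if name else ""
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta mean must lie in (0, 1){label}, got {mean}")
    var = se * se
    if var <= 0.0:
        raise InfeasibleMomentsError(f"beta requires se > 0{label}, got {se}")
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"infeasible moments{label}: se^2={var:g} >= mean(1-mean)={mean * (1 - mean):g}"
        )
    k = mean * (1.0 - mean) / var - 1.0
    return mean * k, (1.0 - mean) * k


def fit_gamma_from_moments(mean: float, se: float, name: str = "") -> tuple[float, float]:
    """Gamma (shape, scale) matching the moments: shape = mean^2/se^2, scale = se^2/mean."""
    label = f" for {name!r}" if name else ""
    if mean <= 0.0 or se <= 0.0:
        raise InfeasibleMomentsError(
            f"gamma requires mean > 0 and se > 0{label}, got mean={mean}, se={se}"
        )
    return mean * mean / (se * se), se * se / mean


def fit_lognormal_from_moments(mean: float, se: float, name: str = "") -> tuple[float, float]:
    """Lognormal (mu, sigma) of the underlying normal matching the moments.

    sigma^2 = ln(1 + se^2/mean^2), mu = ln(mean) - sigma^2/2.
    """
    label = f" for {name!r}" if name else ""
    if mean <= 0.0 or se <= 0.0:
        raise InfeasibleMomentsError(
            f"lognormal requires mean > 0 and se > 0{label}, got mean={mean}, se={se}"
        )
    sigma2 = math.log1p(se * se / (mean * mean))
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def sample_from_moments(
    mean: float,
    se: float,
    family: Family,
    rng: np.random.Generator,
    size=None,
    name: str = "",
):
    """Draw from the method-of-moments fit; se == 0 or family 'fixed' is degenerate."""
    if family == "fixed" or se == 0.0:
        return mean if size is None else np.full(size, mean)
    if family == "beta":
        a, b = fit_beta_from_moments(mean, se, name)
        return rng.beta(a, b, size=size)
    if family == "gamma":
        shape, scale = fit_gamma_from_moments(mean, se, name)
        return rng.gamma(shape, scale, size=size)
    if family == "lognormal":
        mu, sigma = fit_lognormal_from_moments(mean, se, name)
        return rng.lognormal(mu, sigma, size=size)
    raise ValueError(f"unknown family {family!r}")
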