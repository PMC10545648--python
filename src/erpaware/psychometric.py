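"""Probit psychometric fits for staircase data.

The threshold estimate is the opacity at which the fitted probability of an
aware response crosses 0.5.  Fitting is binomial regression with a probit
link on trial-level (opacity, aware) pairs; the location/scale
parameterisation is ``P(aware | x) = Phi((x - mu) / sigma)`` with
``mu = -intercept / slope`` and ``sigma = 1 / slope``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["PsychFit", "fit_probit"]


@dataclass(frozen=True)
class PsychFit:
    """Result of a probit psychometric fit."""

    mu: float
    sigma: float
    mu_se: float
    sigma_se: float
    converged: bool
    n_trials: int

    @classmethod
    def failed(cls, n: int) -> "PsychFit":
        return cls(np.nan, np.nan, np.nan, np.nan, False, n)


def fit_probit(opacities, aware) -> PsychFit:
    """Fit ``P(aware) = Phi((opacity - mu) / sigma)`` by maximum likelihood.

    Returns a non-converged :class:`PsychFit` (never raises) when the data
    cannot identify the threshold: fewer than two distinct opacity levels,
    only one response class (complete separation), a non-positive slope, or
    non-finite estimates.  This mirrors the experimental practice of
    repeating a staircase whose fit does not converge.
    """
    x = np.asarray(opacities, dtype=float)
    y = np.asarray(aware, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("opacities and aware must be 1-D arrays of equal length")
    n = x.size
    if n < 4 or np.unique(x).size < 2 or y.min() == y.max():
        return PsychFit.failed(n)

    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial(
                link=sm.families.links.Probit())).fit(maxiter=200)
        b0, b1 = res.params
        cov = np.asarray(res.cov_params())
    except Exception:
        return PsychFit.failed(n)

    if not (np.isfinite(b0) and np.isfinite(b1)) or b1 <= 0:
        return PsychFit.failed(n)

    mu = -b0 / b1
    sigma = 1.0 / b1
    # delta method: mu = -b0/b1, grad = (-1/b1, b0/b1^2); sigma = 1/b1
    g = np.array([-1.0 / b1, b0 / b1 ** 2])
    mu_var = float(g @ cov @ g)
    sigma_var = float(cov[1, 1] / b1 ** 4)
    if not (np.isfinite(mu) and np.isfinite(mu_var) and mu_var >= 0
            and sigma_var >= 0):
        return PsychFit.failed(n)
    # gradient-based convergence check: huge SEs signal quasi-separation
    if np.sqrt(mu_var) > 10 * (x.max() - x.min() + 1e-12):
        return PsychFit.failed(n)
    return PsychFit(float(mu), float(sigma), float(np.sqrt(mu_var)),
                    float(np.sqrt(sigma_var)), True, n)
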