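"""Gibbs sampler for robust (Student-t) hierarchical linear regression.

The observation model is

    y_i = x_i' beta + z_i' b_{j(i)} + e_i,   e_i ~ t_nu(0, sigma),

with correlated subject-level effects b_j ~ N(0, Sigma).  The Student-t
residual is represented as a scale mixture of normals,
``e_i | w_i ~ N(0, sigma^2 / w_i)`` with ``w_i ~ Gamma(nu/2, nu/2)``, which
makes every update below conditionally conjugate except the degrees of
freedom, which get a random-walk Metropolis step on the log scale.

Priors:

* ``beta_k ~ N(0, prior_scale^2)`` (intercept and slopes alike);
* ``Sigma`` gets the Huang-Wand (2013) hierarchical inverse-Wishart prior
  with ``nu_hw = 2`` and scale ``A_re``, giving marginal half-t(2, A_re)
  distributions on the random-effect SDs;
* ``sigma`` is half-Cauchy(0, A_sigma) via the inverse-gamma mixture
  representation;
* ``nu ~ Gamma(2, rate 0.1)`` truncated to [1, 100].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import gammaln
from scipy.stats import invwishart

__all__ = ["GibbsConfig", "run_gibbs"]

_NU_HW = 2.0       # Huang-Wand degrees of freedom
_A_RE = 2.0        # half-t scale on random-effect SDs
_A_SIGMA = 2.0     # half-Cauchy scale on the residual scale
_NU_LO, _NU_HI = 1.0, 100.0


@dataclass(frozen=True)
class GibbsConfig:
    warmup: int = 500
    draws: int = 1000
    chains: int = 4
    robust: bool = True          # Student-t residuals; False -> Gaussian
    prior_scale: float = 2.0
    nu_proposal_sd: float = 0.3

    @classmethod
    def fast(cls, **kw) -> "GibbsConfig":
        """Reduced-draw preset for multiverse grids and smoke runs."""
        return cls(warmup=300, draws=600, chains=2, **kw)


def _sample_mvn(prec: np.ndarray, lin: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Draw from N(prec^-1 lin, prec^-1) via Cholesky of the precision."""
    c, low = cho_factor(prec, lower=True)
    mean = cho_solve((c, low), lin)
    # solving L' x = z yields a draw with covariance prec^-1
    z = rng.standard_normal(lin.size)
    return mean + solve_triangular(np.tril(c).T, z)


def _log_p_nu(nu: float, w: np.ndarray) -> float:
    n = w.size
    h = nu / 2.0
    return (n * (h * np.log(h) - gammaln(h))
            + (h - 1.0) * np.log(w).sum() - h * w.sum()
            + np.log(nu) - 0.1 * nu)        # Gamma(2, 0.1) prior kernel


def _one_chain(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
               subj: np.ndarray, cfg: GibbsConfig,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    n, p = X.shape
    q = Z.shape[1]
    J = subj.max() + 1
    s2_prior = cfg.prior_scale ** 2
    # per-trial outer products for fast per-subject normal-equation sums
    ZZ = Z[:, :, None] * Z[:, None, :]                  # (n, q, q)
    ZX = Z[:, :, None] * X[:, None, :]                  # (n, q, p)

    # --- initialization: ridge WLS, unit weights, modest scale
    XtX = X.T @ X + np.eye(p) / s2_prior
    beta = np.linalg.solve(XtX, X.T @ y)
    b = np.zeros((J, q))
    resid = y - X @ beta
    sigma2 = max(np.var(resid) / 2.0, 1e-6)
    w = np.ones(n)
    nu = 10.0
    Sigma = np.eye(q)
    Sigma_inv = np.eye(q)
    a_aux = np.ones(q)
    xi = 1.0

    keep = {k: [] for k in ("beta", "sigma", "nu")}

    for it in range(cfg.warmup + cfg.draws):
        sw = w / sigma2
        Xw = X * sw[:, None]

        # per-subject normal-equation blocks
        S = np.empty((J, q, q))                         # Z_j' W_j Z_j + Sigma^-1
        for a in range(q):
            for c in range(a, q):
                s_ac = np.bincount(subj, weights=ZZ[:, a, c] * sw, minlength=J)
                S[:, a, c] = s_ac
                S[:, c, a] = s_ac
        S += Sigma_inv
        A = np.stack([np.column_stack(
            [np.bincount(subj, weights=ZX[:, a, c] * sw, minlength=J)
             for c in range(p)]) for a in range(q)], axis=1)   # (J, q, p)
        u = np.column_stack([
            np.bincount(subj, weights=Z[:, a] * sw * y, minlength=J)
            for a in range(q)])                                # (J, q)

        # beta | y (subject effects marginalized by Woodbury): collapsing
        # the b_j removes the intercept/random-intercept funnel
        SA = np.linalg.solve(S, A)                             # (J, q, p)
        Su = np.linalg.solve(S, u[:, :, None])[:, :, 0]        # (J, q)
        prec = Xw.T @ X + np.eye(p) / s2_prior - np.einsum("jqp,jqr->pr", A, SA)
        prec = 0.5 * (prec + prec.T)
        lin = Xw.T @ y - np.einsum("jqp,jq->p", A, Su)
        beta = _sample_mvn(prec, lin, rng)
        fixed = X @ beta

        # b_j | beta: batched precision-Cholesky sampling
        lin_b = u - np.einsum("jqp,p->jq", A, beta)
        L = np.linalg.cholesky(S)
        Lt = L.transpose(0, 2, 1)
        mean_b = np.linalg.solve(Lt, np.linalg.solve(L, lin_b[:, :, None]))
        zdraw = rng.standard_normal((J, q, 1))
        b = (mean_b + np.linalg.solve(Lt, zdraw))[:, :, 0]
        zb = np.einsum("ij,ij->i", Z, b[subj])

        resid = y - fixed - zb

        if cfg.robust:
            # w_i | rest  and  nu | w (Metropolis on log nu)
            rate = (nu + resid ** 2 / sigma2) / 2.0
            w = rng.gamma((nu + 1.0) / 2.0, 1.0 / rate)
            prop = float(np.exp(np.log(nu) + rng.normal(0.0, cfg.nu_proposal_sd)))
            if _NU_LO <= prop <= _NU_HI:
                log_acc = (_log_p_nu(prop, w) - _log_p_nu(nu, w)
                           + np.log(prop) - np.log(nu))   # log-scale Jacobian
                if np.log(rng.random()) < log_acc:
                    nu = prop

        # sigma^2 | rest (half-Cauchy via IG mixture)
        sigma2 = 1.0 / rng.gamma((n + 1.0) / 2.0,
                                 1.0 / (1.0 / xi + 0.5 * np.sum(w * resid ** 2)))
        xi = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / _A_SIGMA ** 2 + 1.0 / sigma2))

        # Sigma | b, a  (Huang-Wand hierarchical inverse-Wishart)
        scale = 2.0 * _NU_HW * np.diag(1.0 / a_aux) + b.T @ b
        Sigma = invwishart.rvs(df=int(_NU_HW + q - 1 + J), scale=scale,
                               random_state=rng)
        Sigma = np.atleast_2d(Sigma)
        Sigma_inv = np.linalg.inv(Sigma)
        a_aux = 1.0 / rng.gamma((_NU_HW + q) / 2.0,
                                1.0 / (_NU_HW * np.diag(Sigma_inv)
                                       + 1.0 / _A_RE ** 2))

        if it >= cfg.warmup:
            keep["beta"].append(beta.copy())
            keep["sigma"].append(np.sqrt(sigma2))
            keep["nu"].append(nu)

    return {k: np.asarray(v) for k, v in keep.items()}


def run_gibbs(y: np.ndarray, X: np.ndarray, Z: np.ndarray, subj: np.ndarray,
              cfg: GibbsConfig, seed: int | np.random.SeedSequence
              ) -> dict[str, np.ndarray]:
    """Run ``cfg.chains`` independent chains; returns stacked draws.

    Output arrays have shape ``(chains, draws)`` (``beta``:
    ``(chains, draws, p)``).  Chain seeds are spawned deterministically from
    ``seed``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    subj = np.asarray(subj, dtype=int)
    if not (y.size == X.shape[0] == Z.shape[0] == subj.size):
        raise ValueError("inconsistent design dimensions")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    chains = [
        _one_chain(y, X, Z, subj, cfg, np.random.default_rng(s))
        for s in ss.spawn(cfg.chains)
    ]
    return {k: np.stack([c[k] for c in chains]) for k in chains[0]}
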