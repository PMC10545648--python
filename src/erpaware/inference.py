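"""Bayesian inference on trial-level ERP amplitudes and behavior.

Two regression models estimate awareness effects on single-trial window
amplitudes (uV), both with by-subject random intercepts and slopes and
vague Normal(0, 2) priors on intercepts and slopes:

* ``detection_only`` (detection-threshold trials only)::

      amp ~ 1 + awareness + opacity + (1 + awareness + opacity | subject)

* ``full_interaction`` (both thresholds; threshold dummy-coded 0 =
  identification, 1 = detection, awareness 0 = unaware, 1 = aware)::

      amp ~ 1 + threshold*awareness + threshold*opacity
            + (1 + threshold*awareness + threshold*opacity | subject)

  Under this coding the ``awareness`` coefficient is the identification-
  threshold awareness effect and ``threshold:awareness`` is the change of
  that effect from identification to detection.

Residuals are Student-t by default ("robust"); a Gaussian likelihood is
available behind a flag.  Point-null hypothesis tests use Savage-Dickey
density-ratio Bayes factors, complemented by the probability of direction
(pd) and the fraction of the posterior inside a region of practical
equivalence (ROPE, default +/-0.1 uV).  A Bayesian logistic mixed model
(sampled with emcee) checks orientation-report accuracy across awareness
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm

from ._gibbs import GibbsConfig, run_gibbs

__all__ = ["ModelSpec", "ModelFit", "PosteriorSummary", "fit_model",
           "fit_behavior_model", "savage_dickey_bf", "probability_of_direction",
           "rope_fraction", "summarize_coefficient", "bf_label", "GibbsConfig"]

ROPE_DEFAULT = (-0.1, 0.1)
RHAT_THRESHOLD = 1.05


# --------------------------------------------------------------------------
# posterior indices


def savage_dickey_bf(draws: np.ndarray, prior_scale: float = 2.0,
                     at: float = 0.0) -> tuple[float, bool]:
    """Savage-Dickey density-ratio Bayes factor against a point null.

    ``BF10 = p(at | prior) / p(at | posterior)`` for a Normal(0,
    prior_scale) prior.  The posterior density at the null is estimated by
    a Gaussian KDE (Scott bandwidth) over the pooled draws; when the null
    lies more than 2.5 posterior SDs from the posterior mean, KDE sampling
    noise in the tail dominates and a moment-matched normal tail
    approximation is used instead.  Returns ``(bf10, is_lower_bound)``:
    when the posterior density at the null falls below a numerical floor,
    the BF is reported as a lower bound.
    """
    draws = np.ravel(draws)
    if draws.size < 1000:
        raise ValueError("Savage-Dickey estimate needs >= 1000 draws")
    prior_dens = norm.pdf(at, 0.0, prior_scale)
    m, s = draws.mean(), draws.std()
    if s > 0 and abs(at - m) > 2.5 * s:
        post_dens = float(norm.pdf(at, m, s))
    else:
        kde = gaussian_kde(draws)
        post_dens = float(kde(at)[0])
    floor = 1e-10
    if post_dens < floor:
        return prior_dens / floor, True
    return prior_dens / post_dens, False


def probability_of_direction(draws: np.ndarray) -> float:
    """Fraction of the posterior sharing the sign of its median.

    Zeros count with the median's side, so the value lies in [0.5, 1] for
    any sample.
    """
    draws = np.ravel(draws)
    if draws.size < 1:
        raise ValueError("need at least one draw")
    if np.median(draws) >= 0:
        return float(np.mean(draws >= 0))
    return float(np.mean(draws <= 0))


def rope_fraction(draws: np.ndarray, rope: tuple[float, float] = ROPE_DEFAULT
                  ) -> float:
    """Fraction of the full posterior inside the closed ROPE interval."""
    lo, hi = rope
    if lo > hi:
        raise ValueError("rope bounds must be ordered")
    draws = np.ravel(draws)
    return float(np.mean((draws >= lo) & (draws <= hi)))


def bf_label(bf10: float) -> str:
    """Verbal evidence category at the conventional 3 / 10 / 100 cutoffs."""
    for bound, name in ((100.0, "extreme"), (10.0, "strong"), (3.0, "moderate")):
        if bf10 >= bound:
            return f"{name} evidence for H1"
        if bf10 <= 1.0 / bound:
            return f"{name} evidence for H0"
    return "ambiguous"


@dataclass(frozen=True)
class PosteriorSummary:
    """Summary of one coefficient's marginal posterior."""

    name: str
    mean: float
    ci_low: float
    ci_high: float
    bf10: float
    bf01: float
    pd: float
    rope: float
    rhat: float
    ess: float
    bf_is_lower_bound: bool = False
    label: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("name", "mean", "ci_low", "ci_high", "bf10", "bf01", "pd",
                 "rope", "rhat", "ess", "bf_is_lower_bound", "label")}


def _diagnostics(draws_2d: np.ndarray) -> tuple[float, float]:
    """Split-R-hat and bulk ESS via arviz for (chains, draws) arrays."""
    import arviz as az
    da = az.convert_to_dataset(draws_2d[..., None])
    rhat = float(az.rhat(da)["x"].values.ravel()[0])
    ess = float(az.ess(da)["x"].values.ravel()[0])
    return rhat, ess


def summarize_coefficient(name: str, draws_2d: np.ndarray,
                          prior_scale: float = 2.0,
                          rope: tuple[float, float] = ROPE_DEFAULT,
                          diagnostics: bool = True) -> PosteriorSummary:
    """Build a :class:`PosteriorSummary` from (chains, draws) samples.

    For derived contrasts (sums of coefficients) the implied prior is not
    Normal(0, prior_scale); the Savage-Dickey BF is still reported against
    that reference prior and should be read as such.
    """
    pooled = np.ravel(draws_2d)
    mean = float(pooled.mean())
    lo, hi = np.quantile(pooled, [0.025, 0.975])
    bf10, lower = savage_dickey_bf(pooled, prior_scale)
    if diagnostics and draws_2d.ndim == 2 and draws_2d.shape[0] > 1:
        rhat, ess = _diagnostics(draws_2d)
    else:
        rhat, ess = np.nan, float(pooled.size)
    return PosteriorSummary(
        name=name, mean=mean, ci_low=float(lo), ci_high=float(hi),
        bf10=bf10, bf01=1.0 / bf10, pd=probability_of_direction(pooled),
        rope=rope_fraction(pooled, rope), rhat=rhat, ess=ess,
        bf_is_lower_bound=lower, label=bf_label(bf10))


# --------------------------------------------------------------------------
# design matrices


@dataclass(frozen=True)
class ModelSpec:
    """Which regression to fit and under what likelihood/priors."""

    formula_id: str = "full_interaction"   # detection_only | full_interaction
    outcome: str = "van_amp"               # van_amp | lp_amp | correct
    prior_scale: float = 2.0
    likelihood: str = "student_t_robust"   # or "gaussian"
    include_orientation: bool = False

    def __post_init__(self) -> None:
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        if self.formula_id not in ("detection_only", "full_interaction",
                                   "behavior_logistic"):
            raise ValueError(f"unknown formula_id {self.formula_id!r}")


def build_design(trials: pd.DataFrame, spec: ModelSpec
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Assemble (y, X, Z, subject index, fixed-effect names).

    Predictors enter un-standardized (only opacity is block-centered
    upstream).  The random-effect design Z mirrors the fixed design minus
    the orientation column.
    """
    df = trials[trials["staircase"].isin(["detect", "identify"])].copy()
    outlier_col = f"{spec.outcome}_outlier"
    if outlier_col in df.columns:
        df = df[~df[outlier_col].astype(bool)]
    if spec.formula_id == "detection_only":
        df = df[df["threshold_dummy"] == 1]
    if df.empty:
        raise ValueError("empty analysis set")

    aware = df["aware"].to_numpy(dtype=float)
    opac = df["opacity_centered"].to_numpy(dtype=float)
    ones = np.ones(len(df))
    if spec.formula_id == "detection_only":
        cols = [ones, aware, opac]
        names = ["Intercept", "awareness", "opacity"]
    else:
        thr = df["threshold_dummy"].to_numpy(dtype=float)
        cols = [ones, thr, aware, opac, thr * aware, thr * opac]
        names = ["Intercept", "threshold", "awareness", "opacity",
                 "threshold:awareness", "threshold:opacity"]
    Z = np.column_stack(cols)
    if spec.include_orientation:
        cols = cols + [(df["orientation"] == "right").to_numpy(dtype=float)]
        names = names + ["orientation"]
    X = np.column_stack(cols)
    y = df[spec.outcome].to_numpy(dtype=float)
    codes, _ = pd.factorize(df["subject_id"], sort=True)
    return y, X, Z, codes, names


# --------------------------------------------------------------------------
# model fitting


@dataclass
class ModelFit:
    """Posterior draws plus metadata for one fitted model."""

    spec: ModelSpec
    names: list[str]
    beta: np.ndarray               # (chains, draws, p)
    sigma: np.ndarray | None
    nu: np.ndarray | None
    n_obs: int
    n_subjects: int
    converged: bool
    max_rhat: float
    summaries: dict[str, PosteriorSummary] = field(default_factory=dict)

    def coefficient_draws(self, name: str) -> np.ndarray:
        """(chains, draws) samples for a named coefficient or derived
        contrast (``detection_effect`` = awareness + threshold:awareness)."""
        if name == "detection_effect" and "threshold:awareness" in self.names:
            return (self.coefficient_draws("awareness")
                    + self.coefficient_draws("threshold:awareness"))
        if name == "identification_effect" and "threshold:awareness" in self.names:
            return self.coefficient_draws("awareness")
        return self.beta[:, :, self.names.index(name)]

    def summarize(self, extra: tuple[str, ...] = ()) -> dict[str, PosteriorSummary]:
        for nm in list(self.names) + list(extra):
            self.summaries[nm] = summarize_coefficient(
                nm, self.coefficient_draws(nm), self.spec.prior_scale)
        return self.summaries

    def summary_frame(self) -> pd.DataFrame:
        if not self.summaries:
            self.summarize()
        return pd.DataFrame([s.to_dict() for s in self.summaries.values()])


def fit_model(trials: pd.DataFrame, spec: ModelSpec,
              sampler: GibbsConfig | None = None,
              seed: int | np.random.SeedSequence = 0) -> ModelFit:
    """Fit a robust hierarchical regression to trial-level amplitudes.

    Runs multiple Gibbs chains, attaches convergence diagnostics, and flags
    (never silently accepts) non-convergence via ``fit.converged``.
    Identical seed and configuration reproduce the draws exactly.
    """
    if sampler is None:
        sampler = GibbsConfig(robust=spec.likelihood == "student_t_robust",
                              prior_scale=spec.prior_scale)
    y, X, Z, subj, names = build_design(trials, spec)
    if np.unique(subj).size < 2:
        raise ValueError("hierarchical model needs at least two subjects")
    out = run_gibbs(y, X, Z, subj, sampler, seed)
    beta = out["beta"]
    max_rhat = 0.0
    if beta.shape[0] > 1:
        for k in range(beta.shape[2]):
            r, _ = _diagnostics(beta[:, :, k])
            max_rhat = max(max_rhat, r if np.isfinite(r) else np.inf)
    return ModelFit(spec=spec, names=names, beta=beta,
                    sigma=out.get("sigma"), nu=out.get("nu"),
                    n_obs=y.size, n_subjects=int(np.unique(subj).size),
                    converged=max_rhat < RHAT_THRESHOLD or beta.shape[0] == 1,
                    max_rhat=max_rhat)


# --------------------------------------------------------------------------
# behavior model (Bayesian logistic mixed model, emcee backend)


def _logistic_log_prob(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                       subj: np.ndarray, p: int, J: int,
                       prior_scale: float) -> np.ndarray:
    beta = theta[:, :p]
    u = theta[:, p:p + J]
    log_tau = theta[:, p + J]
    tau = np.exp(log_tau)
    eta = X @ beta.T + u[:, subj].T          # (n, walkers)
    # Bernoulli log-likelihood, numerically stable
    ll = -(np.logaddexp(0.0, -eta) * y[:, None]
           + np.logaddexp(0.0, eta) * (1.0 - y[:, None])).sum(axis=0)
    lp = -0.5 * (beta ** 2).sum(axis=1) / prior_scale ** 2
    lp += -0.5 * (u ** 2).sum(axis=1) / tau ** 2 - J * log_tau
    lp += -0.5 * tau ** 2 + log_tau          # half-normal(1) on tau, log-scale
    return ll + lp


def fit_behavior_model(trials: pd.DataFrame, by_threshold: bool = True,
                       prior_scale: float = 2.0,
                       n_steps: int = 2500, n_walkers: int = 64,
                       seed: int = 0) -> dict:
    """Bayesian logistic mixed model of orientation-report accuracy.

    ``correct ~ awareness`` (optionally ``awareness * threshold``) with
    subject random intercepts, Normal(0, prior_scale) priors on the fixed
    effects and a half-normal(1) prior on the random-intercept SD.  Catch
    trials are excluded.  Returns posterior summaries for the fixed effects
    plus estimated condition-wise proportions correct (population level,
    random intercept at 0).
    """
    import emcee

    df = trials[trials["staircase"].isin(["detect", "identify"])].copy()
    df = df.dropna(subset=["correct"])
    y = df["correct"].to_numpy(dtype=float)
    if y.min() == y.max():
        return {"separation": True, "note": "all responses identical; "
                "logistic fit not identified"}
    aware = df["aware"].to_numpy(dtype=float)
    ones = np.ones(len(df))
    if by_threshold:
        thr = df["threshold_dummy"].to_numpy(dtype=float)
        X = np.column_stack([ones, aware, thr, aware * thr])
        names = ["Intercept", "awareness", "threshold", "awareness:threshold"]
    else:
        X = np.column_stack([ones, aware])
        names = ["Intercept", "awareness"]
    subj, _ = pd.factorize(df["subject_id"], sort=True)
    p, J = X.shape[1], int(subj.max() + 1)
    ndim = p + J + 1

    rng = np.random.default_rng(seed)
    p0 = 0.1 * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, _logistic_log_prob,
        args=(y, X, subj, p, J, prior_scale), vectorize=True)
    state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    sampler.run_mcmc(state, n_steps, progress=False)
    burn = n_steps // 2
    chain = sampler.get_chain(discard=burn, thin=2)     # (steps, walkers, dim)
    beta = np.moveaxis(chain[:, :, :p], 0, 1)           # (walkers, steps, p)

    summaries = {}
    for k, nm in enumerate(names):
        summaries[nm] = summarize_coefficient(nm, beta[:, :, k], prior_scale,
                                              diagnostics=False)

    def _prop(cell_x: np.ndarray) -> dict:
        eta = beta.reshape(-1, p) @ cell_x
        pr = 1.0 / (1.0 + np.exp(-eta))
        lo, hi = np.quantile(pr, [0.025, 0.975])
        return {"mean": float(pr.mean()), "ci_low": float(lo),
                "ci_high": float(hi)}

    props = {}
    if by_threshold:
        cells = {"identify_unaware": [1, 0, 0, 0], "identify_aware": [1, 1, 0, 0],
                 "detect_unaware": [1, 0, 1, 0], "detect_aware": [1, 1, 1, 1]}
    else:
        cells = {"unaware": [1, 0], "aware": [1, 1]}
    for nm, x in cells.items():
        props[nm] = _prop(np.asarray(x, dtype=float))
    accept = float(np.mean(sampler.acceptance_fraction))
    return {"separation": False, "summaries": summaries,
            "proportions": props, "n_obs": int(y.size),
            "acceptance_fraction": accept}
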