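"""Posterior indices, Savage-Dickey factors, and hierarchical model fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from erpaware import (GibbsConfig, ModelSpec, fit_behavior_model, fit_model,
                      probability_of_direction, rope_fraction, savage_dickey_bf)
from erpaware._gibbs import run_gibbs
from erpaware.inference import bf_label, summarize_coefficient


class TestSavageDickey:
    def test_posterior_equal_to_prior_gives_bf_one(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0.0, 2.0, 40_000)
        bf, lower = savage_dickey_bf(draws, prior_scale=2.0)
        assert not lower
        assert bf == pytest.approx(1.0, rel=0.1)

    @pytest.mark.parametrize("mean,sd", [
        (2.0, 0.5), (0.5, 0.3), (-1.0, 0.4), (0.0, 1.0), (1.5, 1.0),
        (-0.3, 0.15), (3.0, 1.5),
    ])
    def test_matches_conjugate_normal_oracle(self, mean, sd):
        # closed-form oracle: BF10 = phi(0; 0, 2) / phi(0; mean, sd)
        rng = np.random.default_rng(abs(hash((mean, sd))) % 2**31)
        draws = rng.normal(mean, sd, 60_000)
        expected = norm.pdf(0, 0, 2.0) / norm.pdf(0, mean, sd)
        bf, lower = savage_dickey_bf(draws, prior_scale=2.0)
        assert not lower
        assert bf == pytest.approx(expected, rel=0.10)

    def test_known_example_normal_2_05(self):
        rng = np.random.default_rng(7)
        draws = rng.normal(2.0, 0.5, 80_000)
        bf, _ = savage_dickey_bf(draws, prior_scale=2.0)
        assert bf == pytest.approx(745.6, rel=0.10)

    def test_shrinking_information_sends_bf_to_one(self):
        # conjugate limit: posterior N(0, s) under prior N(0, 2) gives
        # BF10 = s/2 exactly, approaching 1 as the data carry no information
        rng = np.random.default_rng(8)
        for sd in (1.0, 1.5, 1.9, 1.99):
            draws = rng.normal(0.0, sd, 50_000)
            bf, _ = savage_dickey_bf(draws, prior_scale=2.0)
            assert bf == pytest.approx(sd / 2.0, rel=0.08)

    def test_far_posterior_reports_lower_bound(self):
        rng = np.random.default_rng(9)
        draws = rng.normal(50.0, 0.5, 5_000)
        bf, lower = savage_dickey_bf(draws, prior_scale=2.0)
        assert lower and bf > 1e6

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            savage_dickey_bf(np.zeros(100))


class TestCountingIndices:
    def test_pd_all_negative(self):
        assert probability_of_direction(np.array([-3.0, -1.0, -0.2])) == 1.0

    def test_pd_counting_example(self):
        assert probability_of_direction(np.array([-1.0, 2.0, 3.0, 4.0])) == 0.75

    def test_pd_symmetric_sample_near_half(self):
        rng = np.random.default_rng(1)
        assert probability_of_direction(rng.normal(0, 1, 100_000)) == \
            pytest.approx(0.5, abs=0.01)

    def test_pd_equals_direct_count(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(0.3, 1.0, 5000)
        med = np.median(draws)
        direct = np.mean(draws >= 0 if med >= 0 else draws <= 0)
        assert probability_of_direction(draws) == direct

    def test_rope_counting_examples(self):
        assert rope_fraction(np.array([-0.05, 0.05, 0.5])) == pytest.approx(2 / 3)
        assert rope_fraction(np.array([-2.0, -2.0])) == 0.0

    def test_rope_closed_form_normal(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(0.0, 0.05, 200_000)
        expected = norm.cdf(2) - norm.cdf(-2)
        assert rope_fraction(draws) == pytest.approx(expected, abs=0.01)

    def test_rope_equals_direct_count(self):
        rng = np.random.default_rng(4)
        draws = rng.normal(0, 0.2, 3000)
        direct = np.mean((draws >= -0.1) & (draws <= 0.1))
        assert rope_fraction(draws) == direct

    def test_bf_reciprocal_identity_and_labels(self):
        rng = np.random.default_rng(5)
        s = summarize_coefficient("x", rng.normal(1.0, 0.3, (2, 2000)),
                                  diagnostics=False)
        assert s.bf01 == pytest.approx(1.0 / s.bf10)
        assert bf_label(150.0).startswith("extreme")
        assert bf_label(1.0 / 20.0).startswith("strong")
        assert bf_label(1.5) == "ambiguous"


def _mixed_data(seed, n_subj=12, n_per=80, beta=(1.0, -2.0), tau=0.5,
                sigma=2.0, df=None):
    """Small linear mixed dataset: y = b0 + b1*x + u_j0 + u_j1*x + e."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_subj):
        u = rng.normal(0, tau, 2)
        x = rng.normal(0, 1, n_per)
        e = (rng.standard_t(df, n_per) * sigma if df
             else rng.normal(0, sigma, n_per))
        y = beta[0] + u[0] + (beta[1] + u[1]) * x + e
        rows.append(pd.DataFrame(dict(subject=j, x=x, y=y)))
    df_ = pd.concat(rows, ignore_index=True)
    X = np.column_stack([np.ones(len(df_)), df_["x"]])
    return df_["y"].to_numpy(), X, X.copy(), df_["subject"].to_numpy()


class TestGibbsSampler:
    def test_recovers_fixed_effects(self):
        y, X, Z, subj = _mixed_data(0)
        out = run_gibbs(y, X, Z, subj, GibbsConfig(warmup=300, draws=600,
                                                   chains=2), seed=1)
        beta = out["beta"].reshape(-1, 2)
        for k, truth in enumerate((1.0, -2.0)):
            lo, hi = np.quantile(beta[:, k], [0.025, 0.975])
            assert lo < truth < hi

    def test_robust_fit_estimates_heavy_tails(self):
        y, X, Z, subj = _mixed_data(1, df=3)
        out = run_gibbs(y, X, Z, subj, GibbsConfig(warmup=300, draws=600,
                                                   chains=2), seed=2)
        assert np.median(out["nu"]) < 20.0

    def test_seeded_reproducibility(self):
        y, X, Z, subj = _mixed_data(2)
        cfg = GibbsConfig(warmup=50, draws=50, chains=2)
        a = run_gibbs(y, X, Z, subj, cfg, seed=9)
        b = run_gibbs(y, X, Z, subj, cfg, seed=9)
        assert np.array_equal(a["beta"], b["beta"])

    def test_null_effects_covered_by_ci(self):
        y, X, Z, subj = _mixed_data(3, beta=(0.0, 0.0))
        out = run_gibbs(y, X, Z, subj, GibbsConfig(warmup=300, draws=600,
                                                   chains=2), seed=3)
        beta = out["beta"].reshape(-1, 2)
        for k in range(2):
            lo, hi = np.quantile(beta[:, k], [0.025, 0.975])
            assert lo < 0.0 < hi


def _tiny_trials(seed=0, n_subj=6, n_per=120):
    """Trial table with known awareness effects, bypassing epoch simulation."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_subj):
        for sc, thr, eff in (("detect", 1, -2.0), ("identify", 0, -0.5)):
            aware = rng.integers(0, 2, n_per)
            opac = rng.normal(0, 0.3, n_per)
            amp = eff * aware - 3.0 * opac + rng.normal(0, 2.0, n_per)
            rows.append(pd.DataFrame(dict(
                subject_id=j, staircase=sc, threshold_dummy=thr, aware=aware,
                opacity_centered=opac, van_amp=amp, lp_amp=-amp,
                orientation=rng.choice(["left", "right"], n_per),
                correct=rng.integers(0, 2, n_per))))
    return pd.concat(rows, ignore_index=True)


class TestFitModel:
    def test_dummy_coding_identity(self):
        # detection effect from the full model (awareness + interaction)
        # agrees with the detection-only model's awareness coefficient
        trials = _tiny_trials()
        cfg = GibbsConfig(warmup=200, draws=400, chains=2)
        full = fit_model(trials, ModelSpec("full_interaction", "van_amp"),
                         cfg, seed=1)
        det = fit_model(trials, ModelSpec("detection_only", "van_amp"),
                        cfg, seed=2)
        full_eff = full.coefficient_draws("detection_effect").ravel()
        det_eff = det.coefficient_draws("awareness").ravel()
        width = np.quantile(det_eff, 0.975) - np.quantile(det_eff, 0.025)
        assert abs(full_eff.mean() - det_eff.mean()) < width

    def test_interaction_recovered(self):
        trials = _tiny_trials()
        fit = fit_model(trials, ModelSpec("full_interaction", "van_amp"),
                        GibbsConfig(warmup=200, draws=500, chains=2), seed=3)
        draws = fit.coefficient_draws("threshold:awareness").ravel()
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert lo < -1.5 < hi        # truth: -2.0 - (-0.5)
        assert hi < 0.0

    def test_single_subject_rejected(self):
        trials = _tiny_trials(n_subj=1)
        with pytest.raises(ValueError):
            fit_model(trials, ModelSpec("full_interaction", "van_amp"),
                      GibbsConfig(warmup=10, draws=10, chains=1), seed=0)

    def test_orientation_predictor_adds_fixed_effect(self):
        trials = _tiny_trials()
        fit = fit_model(trials, ModelSpec("full_interaction", "van_amp",
                                          include_orientation=True),
                        GibbsConfig(warmup=100, draws=500, chains=1), seed=4)
        assert "orientation" in fit.names
        assert fit.beta.shape[2] == 7


class TestBehaviorModel:
    def test_separation_guard(self):
        trials = _tiny_trials()
        trials["correct"] = 1
        out = fit_behavior_model(trials, seed=0)
        assert out["separation"]

    def test_recovers_condition_proportions(self):
        rng = np.random.default_rng(11)
        rows = []
        probs = {("identify", 0): 0.72, ("identify", 1): 0.97,
                 ("detect", 0): 0.51, ("detect", 1): 0.53}
        for j in range(10):
            for (sc, aware), p in probs.items():
                n = 60
                rows.append(pd.DataFrame(dict(
                    subject_id=j, staircase=sc,
                    threshold_dummy=1 if sc == "detect" else 0,
                    aware=aware, correct=rng.binomial(1, p, n))))
        trials = pd.concat(rows, ignore_index=True)
        out = fit_behavior_model(trials, n_steps=1500, seed=5)
        est = out["proportions"]["identify_aware"]
        assert est["ci_low"] <= 0.97 <= est["ci_high"]
        assert est["mean"] == pytest.approx(0.97, abs=0.03)
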