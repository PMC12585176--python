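"""Decision readout: summary variables, probit stage, fits, permutation."""

import warnings

import numpy as np
import pytest
from scipy.stats import norm

import mcdpop as m
from mcdpop.mcd import PopulationResponse
from mcdpop.params import DecisionParams
from mcdpop.temporal import (DecisionVariables, decision_probability,
                             fit_decision_params, lag_sweep_pairs,
                             permutation_test, psychometric_curve,
                             simulate_counts, summarize)


def _pop(corr, lag, fs=10.0):
    return PopulationResponse(corr=np.asarray(corr, float),
                              lag=np.asarray(lag, float), fs=fs)


class TestSummarize:
    def test_all_zero(self):
        dv = summarize(_pop(np.zeros((2, 2, 4)), np.zeros((2, 2, 4))))
        assert dv.X == 0.0 and dv.Y == 0.0

    def test_grid_sum_arithmetic(self):
        dv = summarize(_pop(np.ones((2, 2, 2)), np.zeros((2, 2, 2))))
        assert dv.X == 8.0

    def test_linearity_in_response_scale(self, rng):
        corr = rng.random((3, 3, 10))
        lag = rng.standard_normal((3, 3, 10))
        a = summarize(_pop(corr, lag))
        b = summarize(_pop(3.0 * corr, 3.0 * lag))
        assert np.isclose(b.X, 3 * a.X) and np.isclose(b.Y, 3 * a.Y)

    def test_window_restriction_and_errors(self):
        corr = np.ones((1, 1, 10))
        dv = summarize(_pop(corr, corr, fs=10.0), window=(0.2, 0.5))
        assert dv.X == 3.0
        with pytest.raises(ValueError, match="window"):
            summarize(_pop(corr, corr, fs=10.0), window=(0.9, 0.9))


class TestDecisionProbability:
    def test_null_betas_give_chance(self):
        assert decision_probability(DecisionVariables(1.0, -2.0),
                                    DecisionParams()) == 0.5

    def test_criterion_only(self):
        p = decision_probability(DecisionVariables(0.0, 0.0),
                                 DecisionParams(beta_crit=1.6449))
        assert np.isclose(p, 0.95, atol=1e-4)

    def test_monotone_in_corr_gain(self):
        beta = DecisionParams(beta_corr=1.0)
        ps = [decision_probability(DecisionVariables(x, 0.0), beta)
              for x in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(ps) > 0)


class TestFitDecisionParams:
    def test_parameter_recovery_within_joint_errors(self, human, rng):
        lags = np.linspace(-0.5, 0.5, 11)
        pairs = [m.make_click_flash(l, duration=2.4, fs=500.0) for l in lags]
        X, Y = lag_sweep_pairs(pairs, human)
        z = lambda a: (a - a.mean()) / a.std()
        true = (-1.0, 0.8, 2.5)
        p = norm.cdf(true[0] + true[1] * z(X) + true[2] * z(Y))
        counts = simulate_counts(p, 200, rng)
        fit = fit_decision_params(X, Y, counts, np.full(11, 200))
        est = np.array([fit.params.beta_crit, fit.params.beta_corr,
                        fit.params.beta_lag])
        assert np.all(np.abs(est - np.array(true)) < 3 * fit.bse)

    def test_flat_responses_give_null_criterion(self):
        X = np.array([0.0, 0.0, 0.0, 0.0])
        Y = np.zeros(4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # degenerate design is expected
            fit = fit_decision_params(X, Y, np.full(4, 50), np.full(4, 100),
                                      use_lag=False)
        assert abs(fit.params.beta_crit) < 0.05

    def test_tied_fit_uses_three_free_parameters(self, human):
        """One decision-parameter set shared across four conditions."""
        X = np.concatenate([np.linspace(0, 1, 7)] * 4)
        Y = np.concatenate([np.linspace(-1, 1, 7)] * 4)
        k = (28 * [10])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_decision_params(X, Y, k, np.full(28, 20))
        assert fit.n_free_params == 3

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_decision_params([1.0, 2.0], [0.0, 0.0], [1, 2], [4, 4])


class TestPsychometricCurves:
    def test_sj_curve_is_unimodal_bell(self, human, click_pair):
        lags = np.linspace(-0.5, 0.5, 21)
        curve = psychometric_curve(click_pair, lags,
                                   DecisionParams(beta_corr=1e10), human,
                                   task="sj")
        p = curve.p_model
        assert np.all((p >= 0) & (p <= 1)) and not np.any(np.isnan(p))
        d = np.sign(np.diff(p))
        assert (np.diff(d[d != 0]) != 0).sum() == 1   # single interior peak

    def test_toj_curve_monotone(self, human, click_pair):
        lags = np.linspace(-0.4, 0.4, 17)
        curve = psychometric_curve(click_pair, lags,
                                   DecisionParams(beta_lag=1e9), human,
                                   task="toj")
        assert np.all(np.diff(curve.p_model) >= 0)

    def test_frequency_doubling_for_periodic_stimuli(self, human):
        """1 Hz square waves: two oscillations of perceived simultaneity per
        phase cycle."""
        phases = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        pairs = [m.make_periodic(1.0, ph, duration=4.0, fs=500.0)
                 for ph in phases]
        X, _ = lag_sweep_pairs(pairs, human)
        p = norm.cdf((X - X.mean()) / X.std())
        maxima = (p > np.roll(p, 1)) & (p >= np.roll(p, -1))
        assert maxima.sum() == 2


class TestPermutation:
    def test_identical_stimuli_degenerate_null(self, human, rng):
        lags = np.linspace(-0.4, 0.4, 9)
        pairs = [m.make_click_flash(l, duration=2.4, fs=200.0) for l in lags]
        X, Y = lag_sweep_pairs(pairs, human)
        z = lambda a: (a - a.mean()) / a.std()
        exps = []
        for seed in range(3):
            counts = simulate_counts(norm.cdf(2 * z(X)), 200,
                                     np.random.default_rng(seed))
            exps.append(m.TemporalExperiment(
                pairs=pairs, lags=lags, n_resp=counts,
                n_trials=np.full(9, 200.0)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = permutation_test(exps, human, n_perm=100, seed=0)
        assert res.null_sd < 1e-12
        assert np.isclose(res.null_mean, res.matched)

    def test_matched_stimuli_beat_null(self, human):
        from mcdpop.synthetic_corpus import make_corpus

        corpus = make_corpus(human, seed=5, n_trials=200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = permutation_test(corpus, human, n_perm=200, seed=1)
        assert res.matched > np.percentile(res.null, 95)
        assert np.isfinite(res.null_mean) and np.isfinite(res.null_sd)

    def test_too_few_experiments_rejected(self, human):
        with pytest.raises(ValueError, match="at least 2"):
            permutation_test([None], human)
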