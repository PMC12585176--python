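"""Spatial readout: MLE fusion, posteriors, causal inference, fixations."""

import numpy as np
import pytest
from scipy.stats import norm

import mcdpop as m
from mcdpop.mcd import mcd_population, transient_channel
from mcdpop.spatial import (GaussianCue, SpatialPosterior, bci_combine,
                            common_cause_probability, distribution_moments,
                            fit_fixation_model, fixation_model,
                            log_corr_total, mle_predict, mle_predict_multi,
                            simulate_blob_localization,
                            simulate_trimodal_blobs, spatial_posterior,
                            unimodal_posterior)


class TestMLEClosedForm:
    def test_variance_product_over_sum(self):
        pred = mle_predict(GaussianCue(0.0, 1.0), GaussianCue(0.0, 4.0))
        assert np.isclose(pred.sigma2_mle, 0.8)

    def test_equal_reliability_splits_weights(self):
        pred = mle_predict(GaussianCue(-3.0, 4.0), GaussianCue(5.0, 4.0))
        assert np.isclose(pred.w_vid, 0.5)
        assert np.isclose(pred.mu_mle, 1.0)

    def test_unreliable_cue_ignored_in_limit(self):
        pred = mle_predict(GaussianCue(2.0, 1.0), GaussianCue(-7.0, 1e9))
        assert np.isclose(pred.mu_mle, 2.0, atol=1e-6)

    def test_fused_variance_below_either_cue(self):
        pred = mle_predict(GaussianCue(0.0, 2.0), GaussianCue(0.0, 5.0))
        assert pred.sigma2_mle <= min(2.0, 5.0)
        assert np.isclose(pred.w_vid + pred.w_aud, 1.0)


class TestSpatialPosterior:
    def _response(self, sv=2.0, sa=8.0, disp=5.0):
        stim = m.make_gaussian_blobs(disp / 2, -disp / 2, sv, sa)
        v = transient_channel(stim.vid, 0.045, stim.fs)
        a = transient_channel(stim.aud, 0.0367, stim.fs, modality="aud")
        return v, a, mcd_population(v, a, 0.18, stim.fs)

    def test_normalization(self):
        _, _, pop = self._response()
        assert np.isclose(spatial_posterior(pop).sum(), 1.0)

    def test_intensity_scale_invariance(self):
        _, _, pop = self._response()
        scaled = m.PopulationResponse(corr=7.3 * pop.corr, lag=pop.lag,
                                      fs=pop.fs)
        np.testing.assert_allclose(spatial_posterior(pop),
                                   spatial_posterior(scaled))

    def test_all_zero_response_rejected(self):
        pop = m.PopulationResponse(corr=np.zeros((5, 4)),
                                   lag=np.zeros((5, 4)), fs=10.0)
        with pytest.raises(ValueError, match="all-zero"):
            spatial_posterior(pop)

    def test_matches_mle_closed_form(self):
        """Calibrated blob simulation reproduces precision-weighted fusion."""
        post = simulate_blob_localization(2.0, 8.0, disparity=5.0)
        mu, sd = distribution_moments(post.x_axis, post.p_bimodal)
        pred = mle_predict(GaussianCue(2.5, 4.0), GaussianCue(-2.5, 64.0))
        s_mle = np.sqrt(pred.sigma2_mle)
        assert abs(mu - pred.mu_mle) < 0.02 * s_mle
        assert abs(sd - s_mle) < 0.02 * s_mle

    def test_uncalibrated_posterior_is_narrower(self):
        post = simulate_blob_localization(2.0, 2.0, calibrate=False)
        _, sd = distribution_moments(post.x_axis, post.p_bimodal)
        s_mle = np.sqrt(mle_predict(GaussianCue(0, 4), GaussianCue(0, 4))
                        .sigma2_mle)
        assert np.isclose(sd, s_mle / np.sqrt(2), rtol=0.02)


class TestUnimodalPosterior:
    def test_sums_to_one_and_peaks_at_blob(self):
        stim = m.make_gaussian_blobs(0.0, 10.0, 2.0, 2.0)
        v = transient_channel(stim.vid, 0.045, stim.fs)
        p = unimodal_posterior(v)
        assert np.isclose(p.sum(), 1.0)
        assert stim.x_axis[np.argmax(p)] == 0.0

    def test_independent_of_other_modality(self):
        a1 = m.make_gaussian_blobs(0.0, 10.0, 2.0, 2.0)
        a2 = m.make_gaussian_blobs(0.0, -10.0, 2.0, 8.0)
        for s1, s2 in [(a1, a2)]:
            v1 = transient_channel(s1.vid, 0.045, s1.fs)
            v2 = transient_channel(s2.vid, 0.045, s2.fs)
            np.testing.assert_allclose(unimodal_posterior(v1),
                                       unimodal_posterior(v2))


class TestCommonCause:
    def _pop(self, disp):
        stim = m.make_gaussian_blobs(disp / 2, -disp / 2, 2.0, 8.0)
        v = transient_channel(stim.vid, 0.045, stim.fs)
        a = transient_channel(stim.aud, 0.0367, stim.fs, modality="aud")
        return mcd_population(v, a, 0.18, stim.fs)

    def test_zero_gain_ignores_stimulus(self):
        p1 = common_cause_probability(self._pop(0.0), beta_crit=0.3,
                                      beta_corr=0.0)
        p2 = common_cause_probability(self._pop(15.0), beta_crit=0.3,
                                      beta_corr=0.0)
        assert np.isclose(p1, p2) and np.isclose(p1, norm.cdf(0.3))

    def test_half_lapse_collapses_to_chance(self):
        p = common_cause_probability(self._pop(3.0), beta_crit=2.0,
                                     beta_corr=1.0, p_lapse=0.5)
        assert np.isclose(p, 0.5)

    def test_monotone_nonincreasing_in_disparity(self):
        lt = [log_corr_total(2.0, 8.0, d) for d in range(0, 21, 2)]
        assert np.all(np.diff(lt) < 0)
        ps = [norm.cdf(10.0 + 1.0 * v) for v in lt]
        assert np.all(np.diff(ps) <= 0)

    def test_zero_response_rejected(self):
        pop = m.PopulationResponse(corr=np.zeros((3, 3)),
                                   lag=np.zeros((3, 3)), fs=10.0)
        with pytest.raises(ValueError, match="zero total"):
            common_cause_probability(pop, 0.0)


class TestBCICombination:
    def _posterior(self, pc):
        x = np.linspace(-10, 10, 41)
        pv = np.exp(-0.5 * (x - 2) ** 2)
        pa = np.exp(-0.5 * ((x + 3) / 2) ** 2)
        pb = np.exp(-0.5 * ((x - 1) / 0.8) ** 2)
        post = SpatialPosterior(x_axis=x, p_bimodal=pb / pb.sum(),
                                p_vid=pv / pv.sum(), p_aud=pa / pa.sum(),
                                p_common=pc)
        return bci_combine(post)

    def test_full_common_cause_gives_fused(self):
        post = self._posterior(1.0)
        np.testing.assert_allclose(post.p_combined_vid, post.p_bimodal)
        np.testing.assert_allclose(post.p_combined_aud, post.p_bimodal)

    def test_no_common_cause_gives_unimodal(self):
        post = self._posterior(0.0)
        np.testing.assert_allclose(post.p_combined_vid, post.p_vid)
        np.testing.assert_allclose(post.p_combined_aud, post.p_aud)

    def test_mixture_is_normalized_and_interpolates(self):
        post = self._posterior(0.4)
        assert np.isclose(post.p_combined_vid.sum(), 1.0)
        assert np.isclose(post.p_combined_aud.sum(), 1.0)
        mu = lambda p: float(np.sum(post.x_axis * p))
        lo, hi = sorted([mu(post.p_vid), mu(post.p_bimodal)])
        assert lo <= mu(post.p_combined_vid) <= hi


class TestFixationModel:
    def test_lapse_bounds_single_fixation_probability(self):
        stim = m.make_gaussian_blobs(0.0, 0.0, 2.0, 8.0)
        v = transient_channel(stim.vid, 0.045, stim.fs)
        a = transient_channel(stim.aud, 0.0367, stim.fs, modality="aud")
        pop = mcd_population(v, a, 0.18, stim.fs)
        post = SpatialPosterior(x_axis=stim.x_axis,
                                p_bimodal=spatial_posterior(pop),
                                p_vid=unimodal_posterior(v),
                                p_aud=unimodal_posterior(a))
        p_single, combined = fixation_model(pop, post, beta_crit=1e3,
                                            beta_corr=1.0, p_lapse=0.15)
        assert np.isclose(p_single, 1 - 0.15)
        assert np.isclose(combined.p_combined_aud.sum(), 1.0)

    def test_lapse_recovery_from_simulated_counts(self, rng):
        disparities = [0.0, 3.0, 6.0, 10.0, 15.0]
        lt = np.array([log_corr_total(2.0, 8.0, d) for d in disparities])
        zc = (lt - lt.mean()) / lt.std()
        true_lapse = 0.12
        p = true_lapse + (1 - 2 * true_lapse) * norm.cdf(0.5 + 2.0 * zc)
        counts = rng.binomial(200, p)
        _, _, lapse = fit_fixation_model(lt, counts, np.full(5, 200))
        assert abs(lapse - true_lapse) < 0.05


class TestTrimodal:
    def test_marginal_matches_three_cue_mle(self):
        sigmas, mus = (2.0, 4.0, 8.0), (3.0, -2.0, 1.0)
        x, p = simulate_trimodal_blobs(sigmas, mus)
        mu, sd = distribution_moments(x, p)
        pred = mle_predict_multi([GaussianCue(mu_i, s**2)
                                  for mu_i, s in zip(mus, sigmas)])
        s_mle = np.sqrt(pred.sigma2_mle)
        assert abs(mu - pred.mu_mle) < 0.02 * s_mle
        assert abs(sd - s_mle) < 0.02 * s_mle
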