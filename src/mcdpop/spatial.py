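"""Spatial readout: location posteriors, MLE fusion, causal inference.

Marginalizing the correlation map over time and applying divisive
normalization,

    p(x) = sum_t corr(x, t) / sum_x sum_t corr(x, t),

turns the population response into a probability distribution over azimuth.
For brief Gaussian cues this bimodal posterior reproduces maximum-likelihood
(precision-weighted) fusion: each modality's spatial profile enters the
correlation product squared, which halves its variance, so injecting
stimulus widths of sqrt(2) x the cue sigmas makes the posterior mean and SD
match the closed-form MLE exactly (the default calibration of
:func:`simulate_blob_localization`).

A common-cause probability is read out from the log-compressed total
correlation output, and perceived unimodal locations follow the
causal-inference mixture

    p_mod(x) = p(C=1) p_bimodal(x) + (1 - p(C=1)) p_unimodal_mod(x).

The lag output plays no role in spatial tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .mcd import PopulationResponse, TransientResponse, mcd_population, \
    transient_channel, trimodal_population
from .params import MCDParams
from .stimgen import default_x_axis, make_gaussian_blobs

__all__ = ["GaussianCue", "MLEPrediction", "SpatialPosterior", "mle_predict",
           "mle_predict_multi", "spatial_posterior", "unimodal_posterior",
           "common_cause_probability", "bci_combine", "fixation_model",
           "fit_fixation_model", "simulate_blob_localization",
           "simulate_trimodal_blobs", "distribution_moments"]

#: Relative epsilon guarding the log10 compression against all-zero input.
_LOG_GUARD = 1e-12


@dataclass(frozen=True)
class GaussianCue:
    """Unimodal Gaussian location cue: mean (deg) and variance (deg^2)."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))


@dataclass(frozen=True)
class MLEPrediction:
    """Closed-form precision-weighted fusion of two Gaussian cues."""

    mu_mle: float
    sigma2_mle: float
    w_vid: float
    w_aud: float


@dataclass
class SpatialPosterior:
    """Normalized location distributions plus the common-cause probability."""

    x_axis: np.ndarray
    p_bimodal: np.ndarray
    p_vid: np.ndarray
    p_aud: np.ndarray
    p_common: float | None = None
    p_combined_vid: np.ndarray | None = None
    p_combined_aud: np.ndarray | None = None


def mle_predict(cue_v: GaussianCue, cue_a: GaussianCue) -> MLEPrediction:
    """Two-cue maximum-likelihood fusion (closed form)."""
    sv2, sa2 = cue_v.sigma2, cue_a.sigma2
    w_vid = (1 / sv2) / (1 / sv2 + 1 / sa2)
    return MLEPrediction(
        mu_mle=w_vid * cue_v.mu + (1 - w_vid) * cue_a.mu,
        sigma2_mle=sv2 * sa2 / (sv2 + sa2),
        w_vid=w_vid, w_aud=1 - w_vid)


def mle_predict_multi(cues: "list[GaussianCue]") -> MLEPrediction:
    """Precision-weighted fusion of any number of Gaussian cues."""
    prec = np.array([1.0 / c.sigma2 for c in cues])
    mus = np.array([c.mu for c in cues])
    w = prec / prec.sum()
    return MLEPrediction(mu_mle=float(w @ mus),
                         sigma2_mle=float(1.0 / prec.sum()),
                         w_vid=float(w[0]), w_aud=float(w[1]))


def _normalize(marginal: np.ndarray, what: str) -> np.ndarray:
    total = marginal.sum()
    if total <= 0:
        raise ValueError(f"all-zero {what}: divisive normalization undefined")
    return marginal / total


def spatial_posterior(resp: PopulationResponse) -> np.ndarray:
    """Time-marginalized, divisively normalized correlation map over x."""
    if resp.corr.ndim != 2:
        raise ValueError("expected an (x, t) population response")
    return _normalize(resp.corr.sum(axis=-1), "correlation response")


def unimodal_posterior(tr: TransientResponse) -> np.ndarray:
    """Time-marginalized, normalized unimodal transient response over x."""
    if tr.resp.ndim != 2:
        raise ValueError("expected an (x, t) transient response")
    return _normalize(tr.resp.sum(axis=-1), f"{tr.modality} transient response")


def common_cause_probability(resp: PopulationResponse, beta_crit: float,
                             beta_corr: float = 1.0,
                             p_lapse: float | None = None) -> float:
    """Probability of a common cause from the log-compressed corr total.

    ``p = Phi(beta_crit + beta_corr * log10 sum corr)``; with a lapse rate
    the probability is bounded into ``[p_lapse, 1 - p_lapse]``.  A relative
    epsilon guards the logarithm; an exactly zero response is an error.
    """
    total = float(resp.corr.sum())
    if total <= 0:
        raise ValueError("zero total correlation response: log-compression "
                         "undefined")
    scale = float(np.abs(resp.corr).max()) * resp.corr.size
    p = float(norm.cdf(beta_crit
                       + beta_corr * np.log10(total + _LOG_GUARD * scale)))
    if p_lapse is not None:
        p = p_lapse + (1.0 - 2.0 * p_lapse) * p
    return p


def bci_combine(posterior: SpatialPosterior) -> SpatialPosterior:
    """Causal-inference mixture of bimodal and unimodal posteriors.

    Fills ``p_combined_vid`` / ``p_combined_aud`` with the convex mixtures
    weighted by ``p_common`` and returns the updated posterior.
    """
    if posterior.p_common is None:
        raise ValueError("posterior.p_common must be set before combining")
    pc = posterior.p_common
    posterior.p_combined_vid = pc * posterior.p_bimodal + (1 - pc) * posterior.p_vid
    posterior.p_combined_aud = pc * posterior.p_bimodal + (1 - pc) * posterior.p_aud
    return posterior


def distribution_moments(x: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Mean and standard deviation of a discrete distribution on ``x``."""
    mu = float(np.sum(x * p))
    var = float(np.sum((x - mu) ** 2 * p))
    return mu, float(np.sqrt(var))


def simulate_blob_localization(sigma_vid: float, sigma_aud: float,
                               disparity: float = 0.0, center: float = 0.0,
                               params: MCDParams | None = None,
                               x_axis: np.ndarray | None = None,
                               fs: float = 1000.0,
                               calibrate: bool = True,
                               beta_crit: float | None = None,
                               beta_corr: float = 1.0,
                               p_lapse: float | None = None,
                               ) -> SpatialPosterior:
    """Localize a brief audiovisual blob pair with the population model.

    ``sigma_vid``/``sigma_aud`` are the modality cue widths (the SDs of the
    unimodal localization distributions to emulate); the visual blob sits at
    ``center + disparity/2`` and the auditory at ``center - disparity/2``.
    With ``calibrate=True`` the stimulus profiles are widened by sqrt(2) so
    the bimodal posterior reproduces the MLE closed form exactly.  When
    ``beta_crit`` is given, the common-cause probability and the
    causal-inference mixtures are also filled in.
    """
    from .params import HUMAN

    params = params or HUMAN
    x_axis = default_x_axis() if x_axis is None else np.asarray(x_axis, float)
    widen = np.sqrt(2.0) if calibrate else 1.0
    stim = make_gaussian_blobs(mu_vid=center + disparity / 2,
                               mu_aud=center - disparity / 2,
                               sigma_vid=widen * sigma_vid,
                               sigma_aud=widen * sigma_aud,
                               x_axis=x_axis, fs=fs)
    v = transient_channel(stim.vid, params.tau_bpv, fs, params.n_fast,
                          params.n_slow, modality="vid")
    a = transient_channel(stim.aud, params.tau_bpa, fs, params.n_fast,
                          params.n_slow, modality="aud")
    pop = mcd_population(v, a, params.tau_lp, fs, params=params)
    post = SpatialPosterior(x_axis=x_axis,
                            p_bimodal=spatial_posterior(pop),
                            p_vid=unimodal_posterior(v),
                            p_aud=unimodal_posterior(a))
    if beta_crit is not None:
        post.p_common = common_cause_probability(pop, beta_crit, beta_corr,
                                                 p_lapse)
        bci_combine(post)
    return post


def log_corr_total(sigma_vid: float, sigma_aud: float, disparity: float,
                   params: MCDParams | None = None, fs: float = 1000.0,
                   calibrate: bool = True) -> float:
    """log10 of the summed correlation response for a blob pair."""
    from .params import HUMAN

    params = params or HUMAN
    widen = np.sqrt(2.0) if calibrate else 1.0
    stim = make_gaussian_blobs(mu_vid=disparity / 2, mu_aud=-disparity / 2,
                               sigma_vid=widen * sigma_vid,
                               sigma_aud=widen * sigma_aud, fs=fs)
    v = transient_channel(stim.vid, params.tau_bpv, fs, modality="vid")
    a = transient_channel(stim.aud, params.tau_bpa, fs, modality="aud")
    pop = mcd_population(v, a, params.tau_lp, fs)
    return float(np.log10(pop.corr.sum()))


def fixation_model(resp: PopulationResponse, posterior: SpatialPosterior,
                   beta_crit: float, beta_corr: float, p_lapse: float,
                   ) -> tuple[float, SpatialPosterior]:
    """Single-fixation probability and predicted gaze distribution.

    The probability of a single (vs. double) fixation is the lapse-bounded
    common-cause probability; the gaze distribution then follows from the
    causal-inference mixture with zero additional free parameters.
    """
    p_single = common_cause_probability(resp, beta_crit, beta_corr, p_lapse)
    posterior.p_common = p_single
    return p_single, bci_combine(posterior)


def fit_fixation_model(log_totals: np.ndarray, n_single: np.ndarray,
                       n_trials: np.ndarray) -> tuple[float, float, float]:
    """ML fit of (beta_crit, beta_corr, p_lapse) to single-fixation counts.

    ``log_totals`` holds log10 of the summed correlation response per
    disparity condition.  The binomial likelihood is maximized with a
    bounded Nelder-Mead search over the lapse-bounded probit model.
    """
    log_totals = np.asarray(log_totals, float)
    zc = (log_totals - log_totals.mean()) / max(np.std(log_totals), 1e-12)
    k = np.asarray(n_single, float)
    n = np.asarray(n_trials, float)

    def nll(theta):
        bc, bcorr, lapse = theta
        p = lapse + (1 - 2 * lapse) * norm.cdf(bc + bcorr * zc)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(k * np.log(p) + (n - k) * np.log(1 - p))

    best = None
    for start in ([0.0, 1.0, 0.1], [0.5, 2.0, 0.02], [-0.5, 0.5, 0.2]):
        res = minimize(nll, start, method="Nelder-Mead",
                       bounds=[(-10, 10), (0, 50), (0.0, 0.5)],
                       options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    bc, bcorr, lapse = best.x
    # report beta on the raw log10 scale for downstream reuse
    sd = max(np.std(log_totals), 1e-12)
    return (float(bc - bcorr * log_totals.mean() / sd), float(bcorr / sd),
            float(lapse))


def simulate_trimodal_blobs(sigmas: "tuple[float, float, float]",
                            mus: "tuple[float, float, float]" = (0.0, 0.0, 0.0),
                            params: MCDParams | None = None,
                            x_axis: np.ndarray | None = None,
                            fs: float = 1000.0, calibrate: bool = True,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Trimodal blob localization: returns (x_axis, normalized marginal).

    Each modality is a brief pulse with a Gaussian spatial profile; the
    sqrt(2) calibration plays the same role as in the bimodal case, making
    the time-marginalized trimodal response match three-cue MLE fusion.
    """
    from .params import HUMAN

    params = params or HUMAN
    x_axis = default_x_axis() if x_axis is None else np.asarray(x_axis, float)
    widen = np.sqrt(2.0) if calibrate else 1.0
    stim_v = make_gaussian_blobs(mus[0], mus[0], widen * sigmas[0],
                                 widen * sigmas[0], x_axis=x_axis, fs=fs)
    stim_a = make_gaussian_blobs(mus[1], mus[1], widen * sigmas[1],
                                 widen * sigmas[1], x_axis=x_axis, fs=fs)
    stim_t = make_gaussian_blobs(mus[2], mus[2], widen * sigmas[2],
                                 widen * sigmas[2], x_axis=x_axis, fs=fs)
    taus = (params.tau_bpv, params.tau_bpa, params.tau_bpa)
    trs = [transient_channel(s.vid, tau, fs, params.n_fast, params.n_slow,
                             modality=m)
           for s, tau, m in zip((stim_v, stim_a, stim_t), taus,
                                ("vid", "aud", "tac"))]
    tri = trimodal_population(*trs, tau_lp=params.tau_lp, fs=fs)
    marginal = tri.resp.sum(axis=-1)
    return x_axis, _normalize(marginal, "trimodal response")
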