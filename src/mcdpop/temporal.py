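"""Temporal decision readout: SJ / TOJ / McGurk psychometric machinery.

The dynamic population maps are compressed into two summary decision
variables, the summed correlation output X and the summed lag output Y, and
mapped to a response probability through a probit decision stage,

    p(resp) = Phi(beta_crit + beta_corr * X + beta_lag * Y).

The same architecture serves simultaneity judgments (p(synchronous)),
temporal order judgments (p(audio first)), and McGurk fusion reports
(p(fusion)); only the fitted coefficients differ.  Decision parameters are
estimated by binomial probit regression (GLM); X and Y are z-scored across
the condition set before fitting, so reported coefficients are on the
standardized scale (gains are scale-absorbing, hence this is observationally
equivalent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .mcd import PopulationResponse, respond
from .params import DecisionParams, MCDParams
from .stimgen import TemporalStimulusPair, shift_audio

__all__ = ["DecisionVariables", "PsychometricCurve", "ProbitFit",
           "TemporalExperiment", "summarize", "decision_probability",
           "lag_sweep", "fit_decision_params", "psychometric_curve",
           "simulate_counts", "permutation_test", "PermutationResult"]


@dataclass(frozen=True)
class DecisionVariables:
    """Summary decision variables: X = summed corr, Y = summed lag."""

    X: float
    Y: float
    window: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.X) and np.isfinite(self.Y)):
            raise ValueError("decision variables must be finite")
        if self.X < 0:
            raise ValueError("X is a sum of nonnegative responses")


@dataclass
class PsychometricCurve:
    """Model (and optionally observed) response probabilities over lag."""

    lags: np.ndarray
    p_model: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    task: str = "sj"
    p_obs: np.ndarray | None = None
    n_trials: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"lag": self.lags, "X": self.X, "Y": self.Y,
             "p_model": self.p_model}
        if self.p_obs is not None:
            d["p_obs"] = self.p_obs
        if self.n_trials is not None:
            d["n"] = self.n_trials
        return pd.DataFrame(d)


@dataclass
class TemporalExperiment:
    """One lag-manipulation experiment: stimuli plus response counts."""

    pairs: list
    lags: np.ndarray
    n_resp: np.ndarray | None = None
    n_trials: np.ndarray | None = None
    task: str = "sj"
    name: str = ""

    @property
    def p_obs(self) -> np.ndarray | None:
        if self.n_resp is None:
            return None
        return np.asarray(self.n_resp) / np.asarray(self.n_trials)


def summarize(resp: PopulationResponse, window: "tuple[float, float] | None" = None,
              ) -> DecisionVariables:
    """Sum corr and lag maps over space and a temporal window (seconds).

    With ``window=None`` the full response extent is used (the stimuli are
    generated with their padding already in place).
    """
    corr, lag = resp.corr, resp.lag
    if window is not None:
        i0 = int(round(window[0] * resp.fs))
        i1 = int(round(window[1] * resp.fs))
        if not 0 <= i0 < i1 <= corr.shape[-1]:
            raise ValueError(f"empty or out-of-range window {window}")
        corr = corr[..., i0:i1]
        lag = lag[..., i0:i1]
    win = None if window is None else window[1] - window[0]
    return DecisionVariables(X=float(corr.sum()), Y=float(lag.sum()),
                             window=win)


def decision_probability(dv: DecisionVariables, beta: DecisionParams) -> float:
    """Probit decision stage: Phi(beta_crit + beta_corr*X + beta_lag*Y)."""
    return float(norm.cdf(beta.beta_crit + beta.beta_corr * dv.X
                          + beta.beta_lag * dv.Y))


def _at_lag(stim, lag: float):
    if isinstance(stim, TemporalStimulusPair):
        return shift_audio(stim, lag)
    from .media_io import apply_lag
    return apply_lag(stim, lag)


def lag_sweep(stim, lags, params: MCDParams, fs: float | None = None,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Compute (X, Y) for a stimulus at each lag of a sweep.

    ``stim`` is a zero-lag :class:`TemporalStimulusPair` or a preprocessed
    :class:`~mcdpop.media_io.AVStimulus`; audio is shifted for each lag.
    """
    X, Y = [], []
    for lag in np.atleast_1d(lags):
        s = _at_lag(stim, float(lag))
        rate = fs or getattr(s, "fs", None) or s.fps
        pop = respond(s.vid, s.aud, params, rate)
        dv = summarize(pop)
        X.append(dv.X)
        Y.append(dv.Y)
    return np.asarray(X), np.asarray(Y)


def _zstats(a: np.ndarray) -> tuple[float, float]:
    sd = float(np.std(a))
    return float(np.mean(a)), (sd if sd > 0 else 1.0)


@dataclass
class ProbitFit:
    """Fitted probit decision stage on standardized decision variables."""

    params: DecisionParams
    bse: np.ndarray                 # standard errors (crit, corr[, lag])
    cov: np.ndarray
    x_stats: tuple[float, float]    # (mean, sd) used to z-score X
    y_stats: tuple[float, float]
    use_lag: bool = True
    separation_flagged: bool = False
    n_free_params: int = 3

    def predict(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        xz = (np.asarray(X) - self.x_stats[0]) / self.x_stats[1]
        yz = (np.asarray(Y) - self.y_stats[0]) / self.y_stats[1]
        b = self.params
        return norm.cdf(b.beta_crit + b.beta_corr * xz + b.beta_lag * yz)


def fit_decision_params(X, Y, n_resp, n_trials, use_lag: bool = True,
                        ) -> ProbitFit:
    """Maximum-likelihood probit regression of response counts on (X, Y).

    Conditions from several curves may be concatenated to tie one set of
    decision parameters across them (as in the distance and loudness
    simulations).  Complete separation is flagged rather than fatal: the fit
    is returned after a bounded number of IRLS steps with a warning.
    """
    import statsmodels.api as sm

    X, Y = np.asarray(X, float), np.asarray(Y, float)
    n_resp = np.asarray(n_resp, float)
    n_trials = np.asarray(n_trials, float)
    if len(X) < 3:
        raise ValueError("need at least 3 conditions to fit 3 parameters")
    xm, xs = _zstats(X)
    ym, ys = _zstats(Y)
    cols = [np.ones_like(X), (X - xm) / xs]
    if use_lag:
        cols.append((Y - ym) / ys)
    design = np.column_stack(cols)
    endog = np.column_stack([n_resp, n_trials - n_resp])
    model = sm.GLM(endog, design,
                   family=sm.families.Binomial(sm.families.links.Probit()))
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(maxiter=50)
        for w in caught:
            if "separation" in str(w.message).lower() or \
                    "convergence" in str(w.message).lower():
                flagged = True
    if flagged:
        warnings.warn("possible complete separation in probit fit; "
                      "coefficients returned after bounded iterations",
                      stacklevel=2)
    coef = res.params
    beta = DecisionParams(beta_crit=float(coef[0]), beta_corr=float(coef[1]),
                          beta_lag=float(coef[2]) if use_lag else 0.0)
    return ProbitFit(params=beta, bse=np.asarray(res.bse),
                     cov=np.asarray(res.cov_params()), x_stats=(xm, xs),
                     y_stats=(ym, ys), use_lag=use_lag,
                     separation_flagged=flagged,
                     n_free_params=design.shape[1])


def psychometric_curve(stim, lags, beta, params: MCDParams, task: str = "sj",
                       fs: float | None = None,
                       observed: "tuple[np.ndarray, np.ndarray] | None" = None,
                       ) -> PsychometricCurve:
    """Model response probability at each lag of a sweep.

    ``beta`` is either raw :class:`DecisionParams` (applied to the raw X, Y)
    or a :class:`ProbitFit` (applied on its standardized scale).
    """
    lags = np.asarray(lags, float)
    X, Y = lag_sweep(stim, lags, params, fs=fs)
    if isinstance(beta, ProbitFit):
        p = beta.predict(X, Y)
    else:
        p = norm.cdf(beta.beta_crit + beta.beta_corr * X + beta.beta_lag * Y)
    curve = PsychometricCurve(lags=lags, p_model=np.asarray(p), X=X, Y=Y,
                              task=task)
    if observed is not None:
        curve.p_obs = np.asarray(observed[0], float)
        curve.n_trials = np.asarray(observed[1])
    return curve


def simulate_counts(p: np.ndarray, n_trials, rng: np.random.Generator,
                    ) -> np.ndarray:
    """Draw binomial response counts from per-condition probabilities."""
    n = np.broadcast_to(np.asarray(n_trials), np.shape(p))
    return rng.binomial(n.astype(int), np.clip(p, 0.0, 1.0))


@dataclass
class PermutationResult:
    """Stimulus-permutation test summary."""

    matched: float
    null: np.ndarray
    null_mean: float = field(init=False)
    null_sd: float = field(init=False)
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_mean = float(np.mean(self.null))
        self.null_sd = float(np.std(self.null))
        ge = int(np.sum(self.null >= self.matched - 1e-12))
        self.p_value = (ge + 1) / (len(self.null) + 1)


def permutation_test(experiments: "list[TemporalExperiment]",
                     params: MCDParams, n_perm: int = 200,
                     seed: int = 0) -> PermutationResult:
    """Fit each experiment's data from mismatched stimuli.

    For every permutation, experiment ``i``'s observed curve is fitted (3
    free decision parameters) using the decision variables of experiment
    ``pi(i)``; the statistic is the mean Pearson correlation between fitted
    and observed curves.  The matched (identity) value is returned alongside
    the permuted null distribution.
    """
    if len(experiments) < 2:
        raise ValueError("need at least 2 experiments to permute stimuli")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    XY = [lag_sweep_pairs(e.pairs, params) for e in experiments]

    def mean_r(assignment):
        rs = []
        for i, j in enumerate(assignment):
            X, Y = XY[j]
            fit = fit_decision_params(X, Y, experiments[i].n_resp,
                                      experiments[i].n_trials)
            rs.append(pearsonr(fit.predict(X, Y), experiments[i].p_obs)[0])
        return float(np.mean(rs))

    matched = mean_r(range(len(experiments)))
    null = np.array([mean_r(rng.permutation(len(experiments)))
                     for _ in range(n_perm)])
    return PermutationResult(matched=matched, null=null)


def lag_sweep_pairs(pairs, params: MCDParams) -> tuple[np.ndarray, np.ndarray]:
    """(X, Y) for a list of pre-built stimulus pairs (one per condition).

    Pairs sharing length and rate are filtered as one batch.
    """
    fs = pairs[0].fs
    if all(np.isclose(p.fs, fs) and len(p.vid) == len(pairs[0].vid)
           for p in pairs):
        vid = np.stack([p.vid for p in pairs])
        aud = np.stack([p.aud for p in pairs])
        pop = respond(vid, aud, params, fs)
        return pop.corr.sum(axis=-1), pop.lag.sum(axis=-1)
    X, Y = [], []
    for pair in pairs:
        pop = respond(pair.vid, pair.aud, params, pair.fs)
        dv = summarize(pop)
        X.append(dv.X)
        Y.append(dv.Y)
    return np.asarray(X), np.asarray(Y)
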