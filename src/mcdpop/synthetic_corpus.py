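"""Synthetic psychophysics corpora for parameter-recovery studies.

Builds a small set of lag-manipulation experiments whose "observed" response
counts are sampled from the model itself at known temporal constants and
known decision parameters.  The corpus mixes simultaneity and temporal-order
tasks and varies the visual/auditory pulse widths across experiments, so the
two band-pass constants are separately identifiable.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .params import MCDParams
from .stimgen import make_click_flash, make_periodic
from .temporal import TemporalExperiment, lag_sweep_pairs, simulate_counts

__all__ = ["make_corpus", "default_lags"]

#: Click/flash designs: (task, (vid width, aud width), standardized betas).
_CLICK_DESIGNS = [
    ("sj",  (0.010, 0.010), (-0.8, 2.0, 0.2)),
    ("sj",  (0.005, 0.040), (-0.5, 1.5, 0.0)),
    ("toj", (0.010, 0.010), (0.0, 0.0, 2.0)),
    ("toj", (0.040, 0.005), (0.2, 0.0, 1.5)),
    ("sj",  (0.020, 0.020), (-1.0, 2.5, 0.0)),
]

#: Periodic designs: (frequency Hz, standardized betas).  The square-wave SJ
#: curve over phase carries a temporal-frequency signature that pins the
#: band-pass constants; a single moderate frequency keeps the cost basin
#: around the generating constants wide enough for global search.
_PERIODIC_DESIGNS = [
    (1.0, (-0.3, 2.0, 0.0)),
]


def default_lags(span: float = 0.4, n: int = 9) -> np.ndarray:
    return np.linspace(-span, span, n)


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = np.std(a)
    return (a - np.mean(a)) / (sd if sd > 0 else 1.0)


def make_corpus(params: MCDParams, seed: int = 0, n_trials: int = 200,
                lags: np.ndarray | None = None, fs: float = 200.0,
                duration: float = 2.4, noise_free: bool = False,
                ) -> "list[TemporalExperiment]":
    """Generate seeded experiments from known temporal constants.

    Each experiment sweeps ``lags`` (default 9 lags over +/-0.4 s) with 200
    trials per lag; responses are binomial draws from the probit decision
    stage applied to the model's standardized decision variables.  With
    ``noise_free=True`` the expected proportions are stored instead of
    sampled counts (then the generating constants have exactly zero
    Pearson cost).
    """
    lags = default_lags() if lags is None else np.asarray(lags, float)
    rng = np.random.default_rng(seed)
    designs = []
    for task, widths, betas in _CLICK_DESIGNS:
        pairs = [make_click_flash(lag=float(l), duration=duration, fs=fs,
                                  widths=widths) for l in lags]
        designs.append((pairs, lags, betas, task,
                        f"{task}-click-v{widths[0]*1e3:.0f}a{widths[1]*1e3:.0f}"))
    for freq, betas in _PERIODIC_DESIGNS:
        phases = np.linspace(0.0, 2 * np.pi, len(lags), endpoint=False)
        pairs = [make_periodic(freq, float(ph), duration=duration, fs=fs)
                 for ph in phases]
        designs.append((pairs, phases, betas, "sj", f"sj-square-{freq}Hz"))

    experiments = []
    for pairs, conds, betas, task, name in designs:
        X, Y = lag_sweep_pairs(pairs, params)
        bc, bx, by = betas
        p = norm.cdf(bc + bx * _zscore(X) + by * _zscore(Y))
        if noise_free:
            n_resp = p * n_trials
        else:
            n_resp = simulate_counts(p, n_trials, rng)
        experiments.append(TemporalExperiment(
            pairs=pairs, lags=np.asarray(conds, float),
            n_resp=np.asarray(n_resp, float),
            n_trials=np.full(len(conds), n_trials, dtype=float), task=task,
            name=name))
    return experiments
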