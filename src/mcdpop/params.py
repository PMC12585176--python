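"""Model parameters and species presets.

The temporal tuning of the population is set by three time constants: one
band-pass constant per modality (``tau_bpv``, ``tau_bpa``) controlling the
unimodal transient channels, and one shared low-pass constant (``tau_lp``)
controlling the temporal memory of each correlation sub-unit.  The filter
orders of the quadrature pair are fixed integers (6 fast, 9 slow).

Sign convention used throughout the package: a lag is the signed audiovisual
onset asynchrony in seconds, with **negative lag = vision first** (audio
delayed) and positive lag = audio first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class MCDParams:
    """Temporal constants of the correlation-detector population.

    Parameters
    ----------
    tau_bpv, tau_bpa:
        Band-pass time constants (seconds) of the visual and auditory
        transient channels.
    tau_lp:
        Time constant (seconds) of the sub-unit low-pass filter.
    n_fast, n_slow:
        Orders of the quadrature biphasic filter pair.
    species:
        Free-text tag identifying the preset.
    """

    tau_bpv: float
    tau_bpa: float
    tau_lp: float
    n_fast: int = 6
    n_slow: int = 9
    species: str = "custom"

    def __post_init__(self) -> None:
        if min(self.tau_bpv, self.tau_bpa, self.tau_lp) <= 0:
            raise ValueError("all time constants must be positive")
        if self.n_fast >= self.n_slow:
            raise ValueError("n_fast must be smaller than n_slow")

    def with_taus(self, tau_bpv: float, tau_bpa: float, tau_lp: float) -> "MCDParams":
        return replace(self, tau_bpv=tau_bpv, tau_bpa=tau_bpa, tau_lp=tau_lp,
                       species="custom")


#: Human preset: band-pass 45 ms (vision) / 36.7 ms (audition), low-pass 180 ms.
HUMAN = MCDParams(tau_bpv=0.045, tau_bpa=0.0367, tau_lp=0.180, species="human")

#: Rat preset: both band-pass constants 10 ms, low-pass 138 ms (roughly four
#: times faster temporal tuning than humans).
RAT = MCDParams(tau_bpv=0.010, tau_bpa=0.010, tau_lp=0.138, species="rat")

#: Alternate human set obtained with a mean-squared-error fitting cost.
HUMAN_MSE = MCDParams(tau_bpv=0.039, tau_bpa=0.042, tau_lp=0.156,
                      species="human-mse")

PRESETS = {"human": HUMAN, "rat": RAT, "human-mse": HUMAN_MSE}


@dataclass(frozen=True)
class DecisionParams:
    """Linear coefficients of the probit decision stage.

    ``p(resp) = Phi(beta_crit + beta_corr * X + beta_lag * Y)`` where X and Y
    are the summed correlation and lag outputs.  ``p_lapse`` is only used by
    fixation-count tasks, where it bounds the response probability into
    ``[p_lapse, 1 - p_lapse]``.
    """

    beta_crit: float = 0.0
    beta_corr: float = 0.0
    beta_lag: float = 0.0
    p_lapse: float | None = None

    def __post_init__(self) -> None:
        import math

        for name in ("beta_crit", "beta_corr", "beta_lag"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.p_lapse is not None and not 0.0 <= self.p_lapse <= 0.5:
            raise ValueError("p_lapse must lie in [0, 0.5]")
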