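"""Unimodal transient channels and the correlation-detector population.

Each unit receives a visual signal from one spatial location and the
auditory envelope (mono audio is broadcast to every location; spatialized
audio uses the matching location).  The unimodal transient channel computes
the quadrature energy

    M_mod = sqrt( (s * f6)^2 + (s * f9)^2 ),

a phase-invariant, nonnegative response to intensity *changes*.  The two
sub-units of each detector low-pass filter the other modality and multiply:

    u1 = M_vid . (M_aud * f_lp),      u2 = M_aud . (M_vid * f_lp),

yielding the correlation and lag outputs

    MCD_corr = u1 . u2   (>= 0),      MCD_lag = u1 - u2   (signed).

MCD_corr measures local spatiotemporal audiovisual correlation; the sign of
MCD_lag tracks which modality led.  The trimodal generalization multiplies
each modality's transient response with its own low-passed copy and takes
the product over modalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import biphasic_kernel, causal_convolve, lowpass_kernel
from .params import MCDParams

__all__ = ["TransientResponse", "PopulationResponse", "TrimodalResponse",
           "transient_channel", "mcd_population", "trimodal_population",
           "respond"]


@dataclass(frozen=True)
class TransientResponse:
    """Nonnegative unimodal transient-channel output, time axis last."""

    resp: np.ndarray
    modality: str
    fs: float

    def __post_init__(self) -> None:
        if self.resp.min() < 0:
            raise ValueError("transient responses are nonnegative by construction")


@dataclass(frozen=True)
class PopulationResponse:
    """Correlation and lag maps of the detector population (time axis last)."""

    corr: np.ndarray
    lag: np.ndarray
    fs: float
    params: MCDParams | None = None

    def __post_init__(self) -> None:
        if self.corr.shape != self.lag.shape:
            raise ValueError("corr and lag must share a shape")

    def spatial_mean_series(self) -> "tuple[np.ndarray, np.ndarray]":
        """(corr, lag) averaged over all spatial axes, as time series."""
        axes = tuple(range(self.corr.ndim - 1))
        return self.corr.mean(axis=axes), self.lag.mean(axis=axes)


@dataclass(frozen=True)
class TrimodalResponse:
    """Nonnegative trimodal coincidence response (time axis last)."""

    resp: np.ndarray
    fs: float


def transient_channel(stim, tau_bp: float, fs: float, n_fast: int = 6,
                      n_slow: int = 9, modality: str = "vid",
                      ) -> TransientResponse:
    """Apply the quadrature transient channel along the last (time) axis.

    Accepts any array shaped (..., t); each leading index is one spatial
    location processed independently.  Zero DC gain of the biphasic pair
    means sustained input decays to zero response.
    """
    stim = np.asarray(stim, dtype=float)
    if not np.all(np.isfinite(stim)):
        raise ValueError("stimulus must be finite")
    k_fast = biphasic_kernel(n_fast, tau_bp, fs)
    k_slow = biphasic_kernel(n_slow, tau_bp, fs)
    resp = np.sqrt(causal_convolve(stim, k_fast) ** 2
                   + causal_convolve(stim, k_slow) ** 2)
    return TransientResponse(resp=resp, modality=modality, fs=float(fs))


def _broadcast_audio(vid: np.ndarray, aud: np.ndarray) -> np.ndarray:
    """Broadcast a mono audio signal over the visual spatial axes."""
    if aud.ndim == vid.ndim:
        if aud.shape != vid.shape:
            raise ValueError(f"shape mismatch after broadcast: vid {vid.shape} "
                             f"vs aud {aud.shape}")
        return aud
    if aud.ndim == 1:
        return np.broadcast_to(aud, vid.shape)
    raise ValueError(f"cannot broadcast audio of shape {aud.shape} onto "
                     f"visual grid {vid.shape}")


def mcd_population(vid_tr: TransientResponse, aud_tr: TransientResponse,
                   tau_lp: float, fs: float | None = None,
                   params: MCDParams | None = None) -> PopulationResponse:
    """Combine transient responses into correlation and lag maps.

    Mono audio (a 1-D transient signal) is shared by every detector; a
    spatialized auditory response must match the visual grid exactly.
    """
    fs = fs or vid_tr.fs
    if not np.isclose(vid_tr.fs, aud_tr.fs):
        raise ValueError("visual and auditory sampling rates differ")
    k_lp = lowpass_kernel(tau_lp, fs)
    v = vid_tr.resp
    a = _broadcast_audio(v, aud_tr.resp)
    # low-passed transients are nonnegative by construction; clamp FFT
    # roundoff so corr = u1*u2 >= 0 holds exactly
    u1 = v * np.maximum(causal_convolve(a, k_lp), 0.0)
    u2 = a * np.maximum(causal_convolve(v, k_lp), 0.0)
    return PopulationResponse(corr=u1 * u2, lag=u1 - u2, fs=float(fs),
                              params=params)


def trimodal_population(vid_tr: TransientResponse, aud_tr: TransientResponse,
                        tac_tr: TransientResponse, tau_lp: float,
                        fs: float | None = None) -> TrimodalResponse:
    """Trimodal coincidence detector over vision, audition and touch.

    Each modality is multiplied by its *own* low-passed transient response
    and the three factors are multiplied; the response is therefore symmetric
    under permutation of the modalities and vanishes whenever any one of them
    is silent over the low-pass memory.  (Unlike the bimodal detector there
    is no lag output: temporal-order opponency is fundamentally pairwise.)
    """
    fs = fs or vid_tr.fs
    if not (np.isclose(vid_tr.fs, aud_tr.fs) and np.isclose(vid_tr.fs, tac_tr.fs)):
        raise ValueError("sampling rates differ across modalities")
    k_lp = lowpass_kernel(tau_lp, fs)
    ref = max((m.resp for m in (vid_tr, aud_tr, tac_tr)), key=lambda r: r.ndim)
    out = np.ones_like(ref, dtype=float)
    for tr in (vid_tr, aud_tr, tac_tr):
        m = _broadcast_audio(ref, tr.resp)
        out = out * (m * np.maximum(causal_convolve(m, k_lp), 0.0))
    return TrimodalResponse(resp=out, fs=float(fs))


def _min_rate(params: MCDParams) -> float:
    """Lowest sampling rate resolving every kernel of the parameter set."""
    t_zero = np.sqrt((params.n_fast + 1) * (params.n_fast + 2))
    return max(20.0 / (t_zero * min(params.tau_bpv, params.tau_bpa)),
               2.0 / params.tau_lp)


def respond(vid, aud, params: MCDParams, fs: float,
            upsample: "int | str" = "auto") -> PopulationResponse:
    """Full pipeline: stimuli -> transient channels -> population response.

    ``vid`` is any array with time last; ``aud`` is either a mono envelope
    (t,) or a grid matching ``vid``.  Movie frame rates are usually too low
    to resolve the temporal kernels, so by default the streams are
    sample-and-hold upsampled to the smallest integer multiple of ``fs``
    that does, filtered there, and the response decimated back to the frame
    times (``upsample=1`` forces native-rate evaluation).
    """
    vid = np.asarray(vid, dtype=float)
    aud = np.asarray(aud, dtype=float)
    if upsample == "auto":
        up = max(1, int(np.ceil(_min_rate(params) / fs)))
    else:
        up = int(upsample)
    if up > 1:
        vid = np.repeat(vid, up, axis=-1)
        aud = np.repeat(aud, up, axis=-1)
    rate = fs * up
    v = transient_channel(vid, params.tau_bpv, rate, params.n_fast,
                          params.n_slow, modality="vid")
    a = transient_channel(aud, params.tau_bpa, rate, params.n_fast,
                          params.n_slow, modality="aud")
    pop = mcd_population(v, a, params.tau_lp, rate, params=params)
    if up > 1:
        pop = PopulationResponse(corr=pop.corr[..., up - 1::up] * up,
                                 lag=pop.lag[..., up - 1::up] * up,
                                 fs=fs, params=params)
    return pop
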