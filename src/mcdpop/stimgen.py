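"""Synthetic stimulus generators.

Every class of stimulus used to exercise the model is generated here from
parameters and a seed, bit-reproducibly: minimalistic click/flash pairs,
periodic square waves, 1-D Gaussian spatial blobs, distance-parameterized
reverberant click envelopes, and a random movie fixture with a region whose
luminance co-modulates with the soundtrack.

Lag convention (package-wide): negative lag = vision first (audio delayed),
positive lag = audio first.  Pulses are placed by their temporal centre, so
mirrored lags produce time-mirrored stimulus pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import square

__all__ = [
    "TemporalStimulusPair",
    "SpatialStimulus1D",
    "ReverberantEnvelope",
    "SyntheticMovieFixture",
    "make_click_flash",
    "make_periodic",
    "make_gaussian_blobs",
    "make_reverberant_click",
    "make_correlated_movie",
    "shift_audio",
]


@dataclass(frozen=True)
class TemporalStimulusPair:
    """Time-only visual/auditory intensity pair on a shared clock.

    ``lag`` records the generating asynchrony in seconds (negative = vision
    first).
    """

    vid: np.ndarray
    aud: np.ndarray
    fs: float
    lag: float = 0.0

    def __post_init__(self) -> None:
        if self.vid.shape != self.aud.shape:
            raise ValueError("vid and aud must have the same length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name, s in (("vid", self.vid), ("aud", self.aud)):
            if s.min() < -1e-12 or s.max() > 1 + 1e-12:
                raise ValueError(f"{name} intensities must lie in [0, 1]")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.vid)) / self.fs

    def to_csv(self, path) -> None:
        pd.DataFrame({"t": self.t, "vid": self.vid, "aud": self.aud}).to_csv(
            path, index=False)


@dataclass(frozen=True)
class SpatialStimulus1D:
    """One horizontal spatial dimension per modality: grids over (x, t)."""

    vid: np.ndarray           # (n_x, n_t)
    aud: np.ndarray           # (n_x, n_t)
    x_axis: np.ndarray        # degrees
    fs: float

    def __post_init__(self) -> None:
        if self.vid.shape != self.aud.shape:
            raise ValueError("vid and aud grids must share a shape")
        if self.vid.shape[0] != len(self.x_axis):
            raise ValueError("x_axis length must match the spatial dimension")
        if self.vid.min() < 0 or self.aud.min() < 0:
            raise ValueError("intensities must be nonnegative")


@dataclass(frozen=True)
class ReverberantEnvelope:
    """Sound-level envelope of a click recorded at ``distance`` metres.

    The direct (onset) component scales as 1/distance while the exponential
    reverberant tail is sample-identical across distances, so the temporal
    centre of mass moves rightward as the source recedes.
    """

    env: np.ndarray
    distance: float
    direct_peak: float
    fs: float

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.env)) / self.fs

    def center_of_mass(self) -> float:
        """First temporal moment of the envelope, in seconds."""
        w = self.env
        return float(np.sum(self.t * w) / np.sum(w))

    def to_csv(self, path) -> None:
        pd.DataFrame({"t": self.t, "value": self.env}).to_csv(path, index=False)


@dataclass(frozen=True)
class SyntheticMovieFixture:
    """Random movie whose target region co-modulates with the soundtrack.

    ``movie`` is a :class:`mcdpop.media_io.AVStimulus`; ``target_region`` is a
    boolean pixel mask; ``fixations`` is a (frame, x, y) table sampling points
    inside the region.  Synthetic stand-in for ecological footage.
    """

    movie: "object"
    target_region: np.ndarray
    fixations: pd.DataFrame
    seed: int


def _rect_pulse(n: int, center: float, width: float, fs: float) -> np.ndarray:
    """Unit-amplitude rectangular pulse of ``width`` s centred at ``center`` s.

    Sample membership is computed in integer arithmetic so the pulse keeps
    exactly ``round(width*fs)`` samples at every placement.
    """
    k = max(1, int(round(width * fs)))
    start = int(np.floor(center * fs - k / 2 + 0.5))
    out = np.zeros(n)
    if start < n and start + k > 0:
        out[max(0, start):min(n, start + k)] = 1.0
    return out


def make_click_flash(lag: float, duration: float = 3.0, fs: float = 1000.0,
                     widths: float | tuple[float, float] = 0.01,
                     ) -> TemporalStimulusPair:
    """Minimalistic click-and-flash pair separated by ``lag`` seconds.

    The flash is centred at the stimulus midpoint; the click centre precedes
    it by ``lag`` (so positive lag = audio first).  Pulse widths are
    configurable (a scalar applies to both modalities).
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz for click/flash stimuli")
    try:
        w_vid, w_aud = widths  # type: ignore[misc]
    except TypeError:
        w_vid = w_aud = float(widths)
    if abs(lag) + max(w_vid, w_aud) >= duration / 2:
        raise ValueError(
            f"lag {lag:+.3f} s too large for a {duration:.3f} s stimulus: "
            "|lag| + width must stay below duration/2")
    n = int(round(duration * fs))
    mid = duration / 2
    vid = _rect_pulse(n, mid, w_vid, fs)
    aud = _rect_pulse(n, mid - lag, w_aud, fs)
    return TemporalStimulusPair(vid=vid, aud=aud, fs=float(fs), lag=float(lag))


def make_periodic(freq: float, phase: float, duration: float = 4.0,
                  fs: float = 500.0) -> TemporalStimulusPair:
    """Square-wave intensity envelopes; audio phase-shifted by ``phase`` rad.

    Both envelopes take values in {0, 1} with 50% duty cycle.  A phase of pi
    makes the audio the within-cycle complement of the video.
    """
    if freq >= fs / 4:
        raise ValueError(f"freq={freq} Hz too high for fs={fs} Hz "
                         "(must stay below fs/4)")
    t = np.arange(int(round(duration * fs))) / fs
    vid = 0.5 * (1.0 + square(2 * np.pi * freq * t))
    aud = 0.5 * (1.0 + square(2 * np.pi * freq * t - phase))
    return TemporalStimulusPair(vid=vid, aud=aud, fs=float(fs), lag=0.0)


def make_gaussian_blobs(mu_vid: float, mu_aud: float, sigma_vid: float,
                        sigma_aud: float, x_axis: np.ndarray | None = None,
                        duration: float = 0.5, fs: float = 1000.0,
                        pulse: float = 0.01, onset: float = 0.05,
                        ) -> SpatialStimulus1D:
    """Brief audiovisual pulses with Gaussian spatial profiles.

    Each modality is a ``pulse``-second flash/burst whose spatial profile is a
    unit-area Gaussian centred at its ``mu`` with its ``sigma`` (degrees); all
    spatial uncertainty is injected into the stimulus.  The default x grid
    spans +/-45 deg at 0.5 deg spacing.
    """
    if sigma_vid <= 0 or sigma_aud <= 0:
        raise ValueError("sigmas must be positive")
    if x_axis is None:
        x_axis = default_x_axis()
    x_axis = np.asarray(x_axis, dtype=float)
    if not (x_axis.min() <= mu_vid <= x_axis.max()
            and x_axis.min() <= mu_aud <= x_axis.max()):
        raise ValueError("blob centres must lie inside the x axis range")
    dx = float(np.min(np.diff(x_axis)))
    if min(sigma_vid, sigma_aud) < dx:
        warnings.warn("blob sigma below grid spacing: spatial profile "
                      "under-resolved", stacklevel=2)

    def profile(mu, sigma):
        g = np.exp(-0.5 * ((x_axis - mu) / sigma) ** 2)
        return g / (np.sum(g) * dx)

    n_t = int(round(duration * fs))
    gate = _rect_pulse(n_t, onset + pulse / 2, pulse, fs)
    vid = np.outer(profile(mu_vid, sigma_vid), gate)
    aud = np.outer(profile(mu_aud, sigma_aud), gate)
    return SpatialStimulus1D(vid=vid, aud=aud, x_axis=x_axis, fs=float(fs))


def default_x_axis() -> np.ndarray:
    """Default azimuth grid: 181 points spanning +/-45 deg at 0.5 deg."""
    return np.linspace(-45.0, 45.0, 181)


def make_reverberant_click(distance: float, fs: float = 1000.0,
                           t_reverb: float = 1.0, decay: float = 10.0,
                           direct_width: float = 0.005,
                           onset: float = 0.05,
                           reference_distance: float = 5.0,
                           ) -> ReverberantEnvelope:
    """Click envelope at ``distance`` metres: direct pulse + fixed reverb tail.

    The direct component is a ``direct_width``-second pulse of amplitude
    ``reference_distance / distance`` (inverse-distance law, so the level is
    1 at the reference distance and grows unboundedly as the source
    approaches); the reverberant tail, an exponential decaying at ``decay``
    1/s over ``t_reverb`` seconds, starts right after the direct pulse and
    is sample-identical across distances.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    n = int(round((onset + direct_width + t_reverb + 0.1) * fs))
    t = np.arange(n) / fs
    direct_peak = reference_distance / distance
    env = direct_peak * _rect_pulse(n, onset + direct_width / 2,
                                    direct_width, fs)
    t0 = onset + direct_width
    tail = np.where((t >= t0) & (t < t0 + t_reverb),
                    0.3 * np.exp(-decay * (t - t0)), 0.0)
    return ReverberantEnvelope(env=env + tail, distance=float(distance),
                               direct_peak=float(direct_peak), fs=float(fs))


def _event_trains(rng: np.random.Generator, n_series: int, n_frames: int,
                  p_event: float = 0.02, sigma: float = 2.0,
                  baseline: float = 0.05) -> np.ndarray:
    """Sparse smooth intensity bursts (speech/clap-like event trains).

    Each series is a train of Gaussian bumps (SD ``sigma`` frames) at
    Bernoulli(``p_event``)-per-frame positions with random amplitudes,
    rescaled into [baseline, 0.9].
    """
    from scipy.ndimage import gaussian_filter1d

    impulses = (rng.random((n_series, n_frames)) < p_event) * \
        rng.uniform(0.5, 1.0, (n_series, n_frames))
    x = gaussian_filter1d(impulses, sigma=sigma, axis=1, mode="constant")
    hi = x.max(axis=1, keepdims=True)
    scale = np.where(hi > 0, (0.9 - baseline) / np.maximum(hi, 1e-12), 0.0)
    return baseline + x * scale


def make_correlated_movie(seed: int, shape: tuple[int, int] = (24, 32),
                          n_frames: int = 600, fps: float = 30.0,
                          region: tuple[slice, slice] | np.ndarray | None = None,
                          noise_sd: float = 0.002,
                          p_event_audio: float = 0.25,
                          p_event_background: float = 0.001,
                          n_fixations_per_frame: int = 5,
                          ) -> SyntheticMovieFixture:
    """Reproducible random movie with an audio-locked target region.

    Pixels inside ``region`` follow an affine function of the audio envelope
    plus independent Gaussian noise; pixels outside carry independent
    event-train series of the same amplitude range with zero correlation
    with the audio.  The audio envelope is a dense, speech-like burst train
    (an event roughly every 4 frames by default) while background events are
    rare, emulating footage where one region moves with the soundtrack
    against a mostly quiet scene.  The fixation table samples points inside
    the region on every frame.
    """
    from .media_io import AVStimulus

    h, w = shape
    if region is None:
        rh, rw = max(2, h // 6), max(2, w // 6)
        region = (slice(h // 3, h // 3 + rh), slice(w // 3, w // 3 + rw))
    mask = np.zeros(shape, dtype=bool)
    if isinstance(region, np.ndarray):
        mask[:] = region.astype(bool)
    else:
        mask[region] = True
    if not mask.any():
        raise ValueError("target region is empty")
    if mask.shape != shape:
        raise ValueError("region mask must match the frame shape")

    rng = np.random.default_rng(seed)
    env = _event_trains(rng, 1, n_frames, p_event=p_event_audio)[0]
    while env.max() <= 0.05:                 # guarantee at least one event
        env = _event_trains(rng, 1, n_frames, p_event=p_event_audio)[0]
    vid = np.empty((h, w, n_frames))
    n_out = int((~mask).sum())
    vid[~mask] = _event_trains(rng, n_out, n_frames,
                               p_event=p_event_background)
    vid[mask] = env[None, :]
    vid += noise_sd * rng.standard_normal(vid.shape)
    np.clip(vid, 0.0, 1.0, out=vid)

    ys, xs = np.nonzero(mask)
    idx = rng.integers(0, len(ys), size=(n_frames, n_fixations_per_frame))
    fixations = pd.DataFrame({
        "frame": np.repeat(np.arange(n_frames), n_fixations_per_frame),
        "x": xs[idx].ravel(),
        "y": ys[idx].ravel(),
    })
    movie = AVStimulus(vid=vid, aud=env.copy(), fps=float(fps),
                       meta={"source": f"synthetic(seed={seed})",
                             "pad": 0.0, "scale": 1.0})
    return SyntheticMovieFixture(movie=movie, target_region=mask,
                                 fixations=fixations, seed=int(seed))


def shift_audio(pair: TemporalStimulusPair, lag: float) -> TemporalStimulusPair:
    """Return a copy of ``pair`` with the audio advanced by ``lag`` seconds.

    Positive lag advances the audio (audio first); vacated samples are
    silent.  The recorded ``lag`` field accumulates.
    """
    k = int(round(lag * pair.fs))
    aud = np.zeros_like(pair.aud)
    if k >= 0:
        if k < len(aud):
            aud[:len(aud) - k] = pair.aud[k:]
    else:
        if -k < len(aud):
            aud[-k:] = pair.aud[:len(aud) + k]
    return TemporalStimulusPair(vid=pair.vid.copy(), aud=aud, fs=pair.fs,
                                lag=pair.lag + lag)
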