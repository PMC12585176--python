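"""Audiovisual saliency maps and gaze scoring.

The correlation map of the population response to footage is itself a
dynamic saliency map: salient pixels are those whose luminance changes in
sync with the soundtrack.  Observed gaze is scored against it by smoothing
fixations into a per-frame probability density p_gaze (Gaussian kernel,
sigma = 14 pixels by default), computing the gaze-weighted mean response

    R_gaze(t) = sum_xy p_gaze(x,y,t) corr(x,y,t)

and expressing its excess over the frame average as a standardized mean
difference, SMD(t) = (R_gaze - frame mean) / frame SD — an effect size that
is invariant to affine rescaling of the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .mcd import respond
from .media_io import AVStimulus
from .params import MCDParams

__all__ = ["GazeDensity", "SaliencyScore", "saliency_map", "gaze_density",
           "gaze_score", "group_delay"]


@dataclass
class GazeDensity:
    """Per-frame fixation probability density over pixels.

    ``density`` is (height, width, n_frames); frames without fixations are
    excluded via ``valid`` and carry all-zero density.
    """

    density: np.ndarray
    valid: np.ndarray
    kernel_sigma: float

    @property
    def n_excluded(self) -> int:
        return int((~self.valid).sum())


@dataclass
class SaliencyScore:
    """Gaze-weighted response and standardized mean difference per frame."""

    frame: np.ndarray
    mcd_at_gaze: np.ndarray
    frame_mean: np.ndarray
    frame_sd: np.ndarray
    smd: np.ndarray
    n_excluded_sd: int = 0

    @property
    def mean_smd(self) -> float:
        return float(np.mean(self.smd))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frame,
                             "mcd_at_gaze": self.mcd_at_gaze,
                             "frame_mean": self.frame_mean,
                             "frame_sd": self.frame_sd, "smd": self.smd})


def group_delay(params: MCDParams) -> float:
    """Display-alignment shift: low-pass peak time + first-lobe peak time.

    Used only to time-align response overlays to the stimulus; the biphasic
    first-lobe peak is located numerically.
    """
    from .filters import biphasic_kernel

    k = biphasic_kernel(params.n_fast, max(params.tau_bpv, params.tau_bpa),
                        fs=2000.0)
    first_lobe_peak = float(np.argmax(k.taps)) / k.fs
    return params.tau_lp + first_lobe_peak


def saliency_map(movie: AVStimulus, params: MCDParams,
                 zscore_frames: bool = False) -> np.ndarray:
    """Correlation map (height, width, n_frames) of the population response.

    Optional per-frame z-scoring is for display only (SMD scoring below is
    already gain/offset invariant).
    """
    pop = respond(movie.vid, movie.aud, params, movie.fps)
    corr = pop.corr
    if zscore_frames:
        mu = corr.mean(axis=(0, 1), keepdims=True)
        sd = corr.std(axis=(0, 1), keepdims=True)
        corr = (corr - mu) / np.where(sd > 0, sd, 1.0)
    return corr


def gaze_density(fixations: pd.DataFrame, frame_shape: tuple[int, int],
                 n_frames: int, sigma: float = 14.0) -> GazeDensity:
    """Gaussian-smoothed, per-frame-normalized fixation density.

    ``fixations`` needs columns (frame, x, y); points outside the frame are
    rejected.  Frames with no fixations are flagged as invalid.
    """
    h, w = frame_shape
    fr = fixations["frame"].to_numpy(dtype=int)
    xs = fixations["x"].to_numpy(dtype=float)
    ys = fixations["y"].to_numpy(dtype=float)
    if len(fr) and ((xs < 0) | (xs >= w) | (ys < 0) | (ys >= h)
                    | (fr < 0) | (fr >= n_frames)).any():
        raise ValueError("fixations outside frame or movie bounds")
    density = np.zeros((h, w, n_frames))
    np.add.at(density, (np.round(ys).astype(int), np.round(xs).astype(int), fr), 1.0)
    density = gaussian_filter(density, sigma=(sigma, sigma, 0.0))
    totals = density.sum(axis=(0, 1))
    valid = totals > 0
    density[..., valid] /= totals[valid]
    density[..., ~valid] = 0.0
    return GazeDensity(density=density, valid=valid, kernel_sigma=sigma)


def gaze_score(corr_map: np.ndarray, density: GazeDensity,
               skip_frames: "np.ndarray | None" = None) -> SaliencyScore:
    """Score a gaze density against a saliency map, frame by frame.

    Frames without fixations, frames listed in ``skip_frames`` (e.g. the
    padding), and frames whose response map is constant (zero SD, undefined
    SMD) are excluded; the latter are counted in ``n_excluded_sd``.
    """
    if corr_map.shape != density.density.shape:
        raise ValueError(f"map shape {corr_map.shape} does not match density "
                         f"shape {density.density.shape}")
    n_frames = corr_map.shape[-1]
    keep = density.valid.copy()
    if skip_frames is not None:
        keep[np.asarray(skip_frames, int)] = False
    mu = corr_map.mean(axis=(0, 1))
    sd = corr_map.std(axis=(0, 1))          # population SD over pixels
    degenerate = keep & (sd == 0)
    keep &= sd > 0
    at_gaze = np.einsum("xyt,xyt->t", density.density, corr_map)
    idx = np.nonzero(keep)[0]
    return SaliencyScore(frame=idx, mcd_at_gaze=at_gaze[idx],
                         frame_mean=mu[idx], frame_sd=sd[idx],
                         smd=(at_gaze[idx] - mu[idx]) / sd[idx],
                         n_excluded_sd=int(degenerate.sum()))
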