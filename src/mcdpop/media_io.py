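"""Audiovisual footage I/O and preprocessing.

The preprocessing pipeline mirrors what the model expects of ecological
footage: grayscale luminance in [0, 1], spatial downscaling (default 15% of
the original size, standing in for Gaussian spatial pooling), an RMS audio
envelope downsampled to the frame rate, 2 s of frozen-frame / silent padding
at onset and offset, and subtraction of the first still frame as luminance
baseline.

Video decoding goes through :mod:`imageio` (any container its installed
plugins can read; multi-page TIFF always works).  Audio is read from a
sidecar WAV file, or from an embedded track when an ffmpeg-backed plugin is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AVStimulus", "preprocess", "load_movie", "apply_lag",
           "read_gaze_table", "read_response_table",
           "write_gaze_table", "write_response_table", "write_movie"]

#: Rec. 601 luma weights for grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class AVStimulus:
    """Preprocessed audiovisual stimulus.

    ``vid`` is a luminance grid of shape (height, width, n_frames); ``aud``
    is the envelope at the frame rate, shape (n_frames,).  After baseline
    subtraction ``vid`` may be negative; before it, both streams lie in
    [0, 1].
    """

    vid: np.ndarray
    aud: np.ndarray
    fps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vid.ndim != 3:
            raise ValueError("vid must be (height, width, n_frames)")
        if self.vid.shape[-1] != len(self.aud):
            raise ValueError("audio length must equal the frame count")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.vid.shape[-1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    @property
    def pad(self) -> float:
        return float(self.meta.get("pad", 0.0))


def _to_gray(frames: np.ndarray) -> np.ndarray:
    """(t, h, w[, c]) uint or float frames -> (t, h, w) luminance in [0, 1]."""
    frames = np.asarray(frames)
    if np.issubdtype(frames.dtype, np.integer):
        frames = frames / float(np.iinfo(frames.dtype).max)
    frames = frames.astype(float)
    if frames.ndim == 4:
        frames = frames[..., :3] @ _LUMA
    return np.clip(frames, 0.0, 1.0)


def _rms_envelope(audio: np.ndarray, audio_fs: float, n_frames: int,
                  fps: float) -> np.ndarray:
    """RMS in non-overlapping windows of one frame duration, scaled to [0,1]."""
    audio = np.asarray(audio, dtype=float)
    if audio.ndim == 2:                      # mix multichannel to mono
        audio = audio.mean(axis=1)
    edges = np.round(np.arange(n_frames + 1) * audio_fs / fps).astype(int)
    edges = np.clip(edges, 0, len(audio))
    env = np.zeros(n_frames)
    for i in range(n_frames):
        seg = audio[edges[i]:edges[i + 1]]
        if seg.size:
            env[i] = np.sqrt(np.mean(seg**2))
    peak = env.max()
    return env / peak if peak > 0 else env


def preprocess(frames: np.ndarray, audio: np.ndarray, audio_fs: float,
               fps: float, scale: float = 0.15, pad: float = 2.0,
               crop: tuple[slice, slice] | None = None,
               meta: dict | None = None) -> AVStimulus:
    """Run the full footage pipeline on in-memory frames and audio samples.

    ``frames`` is (n_frames, height, width[, channels]); ``audio`` is raw
    samples at ``audio_fs``.  ``crop`` optionally removes a static background
    before rescaling.  Returns the baseline-subtracted stimulus.
    """
    from skimage.transform import resize

    frames = _to_gray(frames)
    if frames.shape[0] == 0:
        raise ValueError("zero-length video")
    if crop is not None:
        frames = frames[:, crop[0], crop[1]]
    orig_shape = frames.shape[1:]
    if scale != 1.0:
        out_shape = (max(1, int(round(orig_shape[0] * scale))),
                     max(1, int(round(orig_shape[1] * scale))))
        frames = np.stack([
            resize(f, out_shape, anti_aliasing=True, mode="reflect")
            for f in frames])
    env = _rms_envelope(audio, audio_fs, frames.shape[0], fps)

    n_pad = int(round(pad * fps))
    if n_pad:
        frames = np.concatenate([
            np.repeat(frames[:1], n_pad, axis=0), frames,
            np.repeat(frames[-1:], n_pad, axis=0)])
        env = np.concatenate([np.zeros(n_pad), env, np.zeros(n_pad)])

    baseline = frames[0].copy()
    frames = frames - baseline[None]

    info = {"original_size": orig_shape, "scale": scale, "pad": pad}
    if meta:
        info.update(meta)
    return AVStimulus(vid=np.moveaxis(frames, 0, -1), aud=env, fps=float(fps),
                      meta=info)


def load_movie(path, audio: "str | Path | None" = None, fps: float | None = None,
               scale: float = 0.15, pad: float = 2.0,
               crop: tuple[slice, slice] | None = None) -> AVStimulus:
    """Read footage from disk and preprocess it.

    ``audio`` names a sidecar WAV file; without one, an embedded audio track
    is attempted (requires an ffmpeg-backed imageio plugin) and a clear error
    is raised when no audio source exists.  ``fps`` overrides container
    metadata (mandatory for formats without timing, e.g. TIFF stacks).
    """
    import imageio.v3 as iio
    from scipy.io import wavfile

    path = Path(path)
    frames = iio.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4 and frames.shape[-1] not in (3, 4):
        pass  # already (t, h, w, c) with odd channel count; keep as-is
    if fps is None:
        try:
            fps = float(iio.immeta(path)["fps"])
        except Exception as exc:
            raise ValueError(
                f"{path}: no frame-rate metadata; pass fps=") from exc

    if audio is not None:
        audio_fs, samples = wavfile.read(audio)
        if np.issubdtype(samples.dtype, np.integer):
            samples = samples / float(np.iinfo(samples.dtype).max)
    else:
        raise ValueError(
            f"{path}: no audio source; pass a sidecar WAV via audio= "
            "(embedded-track extraction requires an ffmpeg plugin)")
    return preprocess(frames, samples, audio_fs, fps, scale=scale, pad=pad,
                      crop=crop, meta={"source": str(path)})


def write_movie(stim: AVStimulus, video_path, audio_path=None,
                audio_fs: int = 8000) -> None:
    """Write frames (TIFF stack / any imageio-writable container) + WAV audio."""
    import imageio.v3 as iio
    from scipy.io import wavfile

    frames = np.moveaxis(stim.vid, -1, 0)
    lo, hi = frames.min(), frames.max()
    scaled = (255 * (frames - lo) / (hi - lo if hi > lo else 1.0)).astype(
        np.uint8)
    iio.imwrite(video_path, scaled)
    if audio_path is not None:
        samples = np.repeat(stim.aud, int(round(audio_fs / stim.fps)))
        wavfile.write(audio_path, audio_fs, samples.astype(np.float32))


def apply_lag(stim: AVStimulus, lag: float) -> AVStimulus:
    """Shift the audio stream by ``lag`` seconds (negative = vision first).

    Positive lag advances the audio relative to the video by
    ``round(lag * fps)`` frames; vacated samples are silent.  The shift must
    stay within the padding added at preprocessing.
    """
    if abs(lag) > stim.pad + 1e-9:
        raise ValueError(f"|lag|={abs(lag):.3f} s exceeds the padding "
                         f"({stim.pad:.3f} s)")
    k = int(round(lag * stim.fps))
    aud = np.zeros_like(stim.aud)
    n = len(aud)
    if k >= 0:
        if k < n:
            aud[:n - k] = stim.aud[k:]
    else:
        if -k < n:
            aud[-k:] = stim.aud[:n + k]
    meta = dict(stim.meta)
    meta["lag"] = meta.get("lag", 0.0) + lag
    return AVStimulus(vid=stim.vid, aud=aud, fps=stim.fps, meta=meta)


_GAZE_COLS = ["frame", "x", "y"]
_RESP_COLS = ["condition", "lag", "n_resp", "n_trials"]


def read_gaze_table(path, frame_shape: tuple[int, int] | None = None,
                    n_frames: int | None = None) -> pd.DataFrame:
    """Read a (frame, x, y) fixation table, validating bounds when known.

    Rows outside the frame bounds are flagged in a boolean ``valid`` column.
    An empty file yields an empty table.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_GAZE_COLS + ["valid"])
    missing = [c for c in _GAZE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[_GAZE_COLS].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: malformed rows at lines "
                         f"{(df.index[bad] + 2).tolist()}")
    df = df.astype({"frame": int})
    valid = pd.Series(True, index=df.index)
    if n_frames is not None:
        valid &= (df["frame"] >= 0) & (df["frame"] < n_frames)
    if frame_shape is not None:
        h, w = frame_shape
        valid &= (df["x"] >= 0) & (df["x"] < w) & (df["y"] >= 0) & (df["y"] < h)
    df["valid"] = valid
    return df


def read_response_table(path) -> pd.DataFrame:
    """Read a (condition, lag, n_resp, n_trials) psychophysics count table."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_RESP_COLS)
    missing = [c for c in _RESP_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = (df[_RESP_COLS].isna().any(axis=1) | (df["n_resp"] < 0)
           | (df["n_trials"] <= 0) | (df["n_resp"] > df["n_trials"])
           | (df["n_resp"] % 1 != 0) | (df["n_trials"] % 1 != 0))
    if bad.any():
        raise ValueError(f"{path}: malformed rows at lines "
                         f"{(df.index[bad] + 2).tolist()}")
    return df.astype({"n_resp": int, "n_trials": int})


def write_gaze_table(df: pd.DataFrame, path) -> None:
    df[_GAZE_COLS].to_csv(path, index=False)


def write_response_table(df: pd.DataFrame, path) -> None:
    df[_RESP_COLS].to_csv(path, index=False)
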