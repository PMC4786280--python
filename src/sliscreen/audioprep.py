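"""Recording unification: decode, mono-fold, level-normalize, resample, trim.

Field recordings of children arrive as 16-bit PCM WAV, mono or stereo, at
16 kHz or 44.1 kHz depending on the recorder.  Every analysis stage assumes
mono audio at a common rate and a common loudness level, so preprocessing is
a fixed chain: stereo→mono by channel mean, RMS normalization, resampling to
the canonical 16 kHz, and energy-based trimming of leading/trailing silence.
All operations are idempotent on already-conformant audio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioSignal",
    "AudioFormatError",
    "DegenerateSignalError",
    "read_wav",
    "write_wav",
    "to_mono",
    "normalize_level",
    "resample",
    "trim_silence",
    "preprocess",
    "CANONICAL_RATE_HZ",
    "DEFAULT_RMS_DBFS",
]

#: Canonical internal rate.  Formant and mel-band analysis use at most the
#: 0–8 kHz band, which 16 kHz sampling covers exactly.
CANONICAL_RATE_HZ = 16000

#: Default RMS target, dBFS.
DEFAULT_RMS_DBFS = -23.0


class AudioFormatError(ValueError):
    """Unsupported or malformed audio input."""


class DegenerateSignalError(ValueError):
    """Signal unusable for the requested operation (e.g. all-zero)."""


@dataclass(frozen=True)
class AudioSignal:
    """Mono (or, before folding, multi-channel) audio in [-1, 1] floats.

    ``samples`` is 1-D for mono or (n, channels) for multi-channel audio.
    ``empty`` flags a signal that trimming reduced to nothing; callers decide
    whether that is an error.
    """

    samples: np.ndarray
    sample_rate_hz: float
    empty: bool = False

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("audio contains NaN/Inf samples")
        object.__setattr__(self, "samples", arr)

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def __len__(self) -> int:
        return self.samples.shape[0]


def read_wav(path: str | Path) -> AudioSignal:
    """Read a PCM WAV file into float samples in [-1, 1].

    Raises
    ------
    AudioFormatError
        If the file is not a readable WAV, or has an empty payload.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise AudioFormatError(f"cannot decode {path} as WAV: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"{path}: empty audio payload")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"{path}: unsupported sample encoding {data.dtype}")
    return AudioSignal(samples, float(rate))


def write_wav(signal: AudioSignal, path: str | Path) -> Path:
    """Write mono audio as 16-bit PCM WAV (little-endian)."""
    path = Path(path)
    if signal.n_channels != 1:
        raise AudioFormatError("write_wav writes mono only; fold with to_mono first")
    clipped = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, int(signal.sample_rate_hz), pcm)
    return path


def to_mono(signal: AudioSignal) -> AudioSignal:
    """Fold to one channel by the per-sample channel mean."""
    if signal.n_channels == 1:
        return signal
    if signal.n_channels == 2:
        return replace(signal, samples=signal.samples.mean(axis=1))
    raise AudioFormatError(
        f"unsupported channel layout: {signal.n_channels} channels (mono/stereo only)"
    )


def normalize_level(signal: AudioSignal, target_dbfs: float = DEFAULT_RMS_DBFS) -> AudioSignal:
    """Scale so the RMS level equals ``target_dbfs`` (dB re full scale)."""
    rms = float(np.sqrt(np.mean(np.square(signal.samples))))
    if rms == 0.0:
        raise DegenerateSignalError("cannot normalize an all-zero signal")
    target_rms = 10.0 ** (target_dbfs / 20.0)
    return replace(signal, samples=signal.samples * (target_rms / rms))


def resample(signal: AudioSignal, target_rate_hz: int = CANONICAL_RATE_HZ) -> AudioSignal:
    """Polyphase resampling; identity when already at the target rate."""
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    src = int(round(signal.sample_rate_hz))
    if src == target_rate_hz:
        return signal
    g = np.gcd(src, target_rate_hz)
    out = resample_poly(signal.samples, target_rate_hz // g, src // g, axis=0)
    return AudioSignal(out, float(target_rate_hz))


def trim_silence(
    signal: AudioSignal,
    threshold_db: float = -40.0,
    frame_s: float = 0.025,
) -> AudioSignal:
    """Drop leading/trailing frames whose energy is below ``threshold_db``
    relative to the loudest frame.

    A signal trimmed to nothing is returned with ``empty=True`` rather than
    raising — the caller decides how to treat an all-silent recording.
    """
    x = signal.samples
    if x.ndim != 1:
        raise AudioFormatError("trim_silence expects mono audio")
    frame_len = max(1, int(round(frame_s * signal.sample_rate_hz)))
    n_frames = int(np.ceil(len(x) / frame_len)) if len(x) else 0
    if n_frames == 0:
        return replace(signal, empty=True)
    padded = np.pad(x, (0, n_frames * frame_len - len(x)))
    frames = padded.reshape(n_frames, frame_len)
    energy = np.mean(np.square(frames), axis=1)
    peak = energy.max()
    if peak == 0.0:
        return replace(signal, samples=x[:0], empty=True)
    keep = energy >= peak * 10.0 ** (threshold_db / 10.0)
    idx = np.flatnonzero(keep)
    start = idx[0] * frame_len
    stop = min(len(x), (idx[-1] + 1) * frame_len)
    return replace(signal, samples=x[start:stop], empty=False)


def preprocess(
    signal: AudioSignal,
    target_rate_hz: int = CANONICAL_RATE_HZ,
    target_dbfs: float = DEFAULT_RMS_DBFS,
    trim_threshold_db: float = -40.0,
) -> AudioSignal:
    """The full unification chain: mono → resample → trim → RMS normalize."""
    out = to_mono(signal)
    out = resample(out, target_rate_hz)
    out = trim_silence(out, trim_threshold_db)
    if out.empty or len(out) == 0:
        return out
    return normalize_level(out, target_dbfs)
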