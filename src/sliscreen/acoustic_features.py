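"""The large per-utterance acoustic feature set (1,582 dimensions).

The vector follows the structure of the classic 'emobase2010'-style brute
force descriptor set used for paralinguistic classification:

* 34 low-level descriptor (LLD) contours per frame — loudness (1), MFCC 0–14
  (15), log mel-band power over 8 bands spanning 0–8 kHz (8), 8 line spectral
  pair frequencies from an order-8 LPC fit (8), the smoothed-F0 envelope (1)
  and the unclipped voicing probability (1) — plus their 34 regression-delta
  contours;
* 21 statistical functionals applied to each of the 68 contours
  (1,428 features);
* 19 functionals (the 21 minus the two position functionals) applied to the
  4 pitch LLD contours (F0, local jitter, DDP jitter, local shimmer) and
  their deltas (152 features);
* the number of pitch onsets and the total duration (2 features).

Framing is 25 ms Hamming windows with a 10 ms hop throughout.  The set is a
structural reimplementation of the documented feature names, counts and
definitions — no attempt is made to be bit-compatible with any external
extractor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.fft import rfft
from scipy.fft import dct

from . import _dsp
from .audioprep import AudioSignal
from .formantlab import _f0_and_voicing

__all__ = [
    "LLDMatrix",
    "FeatureVector",
    "FUNCTIONALS",
    "FUNCTIONAL_NAMES",
    "REDUCED_FUNCTIONAL_NAMES",
    "BASE_LLD_NAMES",
    "PITCH_LLD_NAMES",
    "compute_functional",
    "delta_coefficients",
    "lsp_from_lpc",
    "compute_base_lld",
    "compute_pitch_lld",
    "assemble_feature_vector",
    "extract_features",
    "TOTAL_FEATURES",
    "MAIN_BLOCK",
    "PITCH_BLOCK",
    "APPENDED",
]

LOG_FLOOR = 1e-10
TOTAL_FEATURES = 1582
MAIN_BLOCK = 1428
PITCH_BLOCK = 152
APPENDED = 2


# ---------------------------------------------------------------------------
# Functionals (the 21-entry registry)
# ---------------------------------------------------------------------------

def _linreg(x: np.ndarray) -> tuple[float, float]:
    """Least-squares (slope, offset) of the contour over frame index."""
    n = len(x)
    if n == 1:
        return 0.0, float(x[0])
    t = np.arange(n, dtype=np.float64)
    slope, offset = np.polyfit(t, x, 1)
    return float(slope), float(offset)


def _linreg_residuals(x: np.ndarray) -> np.ndarray:
    slope, offset = _linreg(x)
    t = np.arange(len(x), dtype=np.float64)
    return x - (slope * t + offset)


def _stddev(x: np.ndarray) -> float:
    return float(np.std(x))


def _skewness(x: np.ndarray) -> float:
    s = np.std(x)
    if s == 0:
        return 0.0
    return float(np.mean(((x - np.mean(x)) / s) ** 3))


def _kurtosis(x: np.ndarray) -> float:
    # raw (non-excess) 4th standardized moment
    s = np.std(x)
    if s == 0:
        return 0.0
    return float(np.mean(((x - np.mean(x)) / s) ** 4))


def _percentile(x: np.ndarray, q: float) -> float:
    return float(np.percentile(x, q, method="linear"))


def _upleveltime(x: np.ndarray, level_pct: float) -> float:
    """Percent of frames strictly above (level_pct * range + min).  A
    constant contour has zero range, so nothing is strictly above: 0."""
    lo, hi = float(np.min(x)), float(np.max(x))
    level = lo + level_pct * (hi - lo)
    return 100.0 * float(np.mean(x > level))


FUNCTIONALS: dict[str, Callable[[np.ndarray], float]] = {
    "maxPos": lambda x: float(np.argmax(x)),
    "minPos": lambda x: float(np.argmin(x)),
    "amean": lambda x: float(np.mean(x)),
    "linregc1": lambda x: _linreg(x)[0],
    "linregc2": lambda x: _linreg(x)[1],
    "linregerrA": lambda x: float(np.mean(np.abs(_linreg_residuals(x)))),
    "linregerrQ": lambda x: float(np.mean(np.square(_linreg_residuals(x)))),
    "stddev": _stddev,
    "skewness": _skewness,
    "kurtosis": _kurtosis,
    "quartile1": lambda x: _percentile(x, 25.0),
    "quartile2": lambda x: _percentile(x, 50.0),
    "quartile3": lambda x: _percentile(x, 75.0),
    "iqr1-2": lambda x: _percentile(x, 50.0) - _percentile(x, 25.0),
    "iqr2-3": lambda x: _percentile(x, 75.0) - _percentile(x, 50.0),
    "iqr1-3": lambda x: _percentile(x, 75.0) - _percentile(x, 25.0),
    "percentile1.0": lambda x: _percentile(x, 1.0),
    "percentile99.0": lambda x: _percentile(x, 99.0),
    "pctlrange0-1": lambda x: _percentile(x, 99.0) - _percentile(x, 1.0),
    "upleveltime75": lambda x: _upleveltime(x, 0.75),
    "upleveltime90": lambda x: _upleveltime(x, 0.90),
}

FUNCTIONAL_NAMES: tuple[str, ...] = tuple(FUNCTIONALS)
#: The pitch block drops the two position functionals.
REDUCED_FUNCTIONAL_NAMES: tuple[str, ...] = tuple(
    n for n in FUNCTIONAL_NAMES if n not in ("maxPos", "minPos")
)

BASE_LLD_NAMES: tuple[str, ...] = (
    ("pcm_loudness",)
    + tuple(f"mfcc[{i}]" for i in range(15))
    + tuple(f"logMelFreqBand[{i}]" for i in range(8))
    + tuple(f"lspFreq[{i}]" for i in range(8))
    + ("F0finEnv", "voicingFinalUnclipped")
)

PITCH_LLD_NAMES: tuple[str, ...] = ("F0final", "jitterLocal", "jitterDDP", "shimmerLocal")


def compute_functional(name: str, contour: np.ndarray) -> float:
    """Apply one registry functional to a non-empty contour."""
    if name not in FUNCTIONALS:
        raise KeyError(f"unknown functional {name!r}; registry has {list(FUNCTIONALS)}")
    contour = np.asarray(contour, dtype=np.float64)
    if contour.size == 0:
        raise ValueError(f"functional {name!r} applied to an empty contour")
    return FUNCTIONALS[name](contour)


# ---------------------------------------------------------------------------
# Delta coefficients
# ---------------------------------------------------------------------------

def delta_coefficients(contour: np.ndarray, window: int = 2) -> np.ndarray:
    """Regression delta over +/- ``window`` frames with edge replication.

    For an exactly linear contour the interior deltas equal the slope.
    Length is preserved; odd symmetry delta(-x) = -delta(x) holds.
    """
    x = np.asarray(contour, dtype=np.float64)
    if x.size == 0:
        return x.copy()
    w = int(window)
    padded = np.pad(x, (w, w), mode="edge")
    num = np.zeros_like(x)
    for k in range(1, w + 1):
        num += k * (padded[w + k : w + k + len(x)] - padded[w - k : w - k + len(x)])
    return num / (2 * sum(k * k for k in range(1, w + 1)))


# ---------------------------------------------------------------------------
# Line spectral pairs
# ---------------------------------------------------------------------------

def lsp_from_lpc(lpc_coeffs: np.ndarray) -> np.ndarray:
    """Line spectral pair frequencies of an order-p LPC polynomial.

    Forms the palindromic sum/difference polynomials
    P(z) = A(z) + z^-(p+1) A(1/z) and Q(z) = A(z) - z^-(p+1) A(1/z),
    deflates their trivial roots at z = -1 / z = +1, and returns the p root
    angles in (0, pi) as ascending angular frequencies (rad/sample).  P and
    Q roots interlace on the unit circle for any stable A.
    """
    a = np.asarray(lpc_coeffs, dtype=np.float64)
    if a[0] != 1.0:
        a = a / a[0]
    p = len(a) - 1
    roots_a = np.roots(a)
    if np.any(np.abs(roots_a) >= 1.0 + 1e-8):
        raise ValueError("unstable LPC polynomial: root on/outside the unit circle")
    ext = np.concatenate([a, [0.0]])
    P = ext + ext[::-1]
    Q = ext - ext[::-1]
    # deflate trivial roots: P has z = -1, Q has z = +1 (even p)
    P_def = np.polynomial.polynomial.polydiv(P[::-1], [1.0, 1.0])[0][::-1]
    Q_def = np.polynomial.polynomial.polydiv(Q[::-1], [-1.0, 1.0])[0][::-1]
    freqs = []
    for poly in (P_def, Q_def):
        r = np.roots(poly)
        ang = np.angle(r)
        freqs.extend(ang[(ang > 1e-9) & (ang < np.pi - 1e-9)])
    freqs = np.sort(np.asarray(freqs))
    if len(freqs) != p:
        raise ValueError(f"expected {p} LSP frequencies, found {len(freqs)}")
    return freqs


def _uniform_lsp(order: int) -> np.ndarray:
    """Flat-spectrum (trivial predictor) limit: uniformly spaced LSFs."""
    return np.pi * np.arange(1, order + 1) / (order + 1)


# ---------------------------------------------------------------------------
# LLD matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LLDMatrix:
    """Framewise contour matrix: 34 base + 34 delta columns."""

    values: np.ndarray  # (n_frames, 68)
    column_names: tuple[str, ...]
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != 68:
            raise ValueError(f"LLDMatrix needs 68 columns, got {self.values.shape}")
        if len(self.column_names) != 68:
            raise ValueError("need 68 column names")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft: int, fs: float, f_hi: float) -> np.ndarray:
    """Triangular mel filters (n_filters, n_fft//2 + 1) spanning 0..f_hi."""
    f_hi = min(f_hi, fs / 2.0)
    mel_pts = np.linspace(0.0, float(_hz_to_mel(f_hi)), n_filters + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    bins = np.floor((n_fft + 1) * hz_pts / fs).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        if mid == lo:
            mid = lo + 1
        if hi <= mid:
            hi = mid + 1
        for b in range(lo, min(mid, fb.shape[1])):
            fb[i, b] = (b - lo) / (mid - lo)
        for b in range(mid, min(hi, fb.shape[1])):
            fb[i, b] = (hi - b) / (hi - mid)
    return fb


def _median5(x: np.ndarray) -> np.ndarray:
    if len(x) < 3:
        return x.copy()
    padded = np.pad(x, (2, 2), mode="edge")
    return np.median(np.lib.stride_tricks.sliding_window_view(padded, 5), axis=1)


def compute_base_lld(signal: AudioSignal, n_fft: int = 512) -> LLDMatrix:
    """The 34 base LLD contours plus their 34 deltas (68 columns).

    Loudness is the framewise RMS normalized to the loudest frame, raised to
    the 0.3 power.  Mel analysis spans 0–8 kHz: a 26-triangle bank feeds the
    15 MFCCs, a separate 8-band bank gives the log mel-band powers.  The LSP
    frequencies come from an order-8 autocorrelation LPC fit per frame.  The
    F0 envelope is the median-of-5 smoothed contour with unvoiced gaps held
    at the last voiced value; the voicing probability is the normalized
    autocorrelation peak, reported unclipped (not zeroed below the voicing
    threshold).
    """
    if signal.samples.ndim != 1:
        raise ValueError("compute_base_lld expects mono audio")
    fs = signal.sample_rate_hz
    frames = _dsp.frame_signal(signal.samples, fs)
    if frames.shape[0] == 0:
        raise ValueError(
            f"signal too short: {len(signal.samples)} samples < one "
            f"{_dsp.FRAME_S * 1000:.0f} ms frame"
        )
    n_frames = frames.shape[0]
    window = np.hamming(frames.shape[1])

    rms = np.sqrt(np.mean(np.square(frames), axis=1))
    peak = rms.max()
    loudness = (rms / peak) ** 0.3 if peak > 0 else np.zeros(n_frames)

    spec = np.abs(rfft(frames * window, n=n_fft, axis=1)) ** 2
    fb26 = _mel_filterbank(26, n_fft, fs, 8000.0)
    fb8 = _mel_filterbank(8, n_fft, fs, 8000.0)
    mel26 = np.log(np.maximum(spec @ fb26.T, LOG_FLOOR))
    mfcc = dct(mel26, type=2, norm="ortho", axis=1)[:, :15]
    logmel8 = np.log(np.maximum(spec @ fb8.T, LOG_FLOOR))

    lsp = np.empty((n_frames, 8))
    pre = _dsp.preemphasize(signal.samples)
    pre_frames = _dsp.frame_signal(pre, fs)
    for i in range(n_frames):
        a = _dsp.lpc(pre_frames[i] * window, 8)
        try:
            lsp[i] = lsp_from_lpc(a)
        except ValueError:
            lsp[i] = _uniform_lsp(8)

    f0, voicing = _f0_and_voicing(signal, (60.0, 500.0), 0.45)
    f0 = f0[:n_frames]
    voicing = voicing[:n_frames]
    env = _median5(f0)
    # hold the last voiced value through unvoiced gaps (envelope semantics)
    held = env.copy()
    last = 0.0
    for i in range(len(held)):
        if held[i] > 0:
            last = held[i]
        else:
            held[i] = last

    base = np.column_stack([loudness, mfcc, logmel8, lsp, held, voicing])
    deltas = np.column_stack([delta_coefficients(base[:, j]) for j in range(base.shape[1])])
    names = BASE_LLD_NAMES + tuple(f"{n}_de" for n in BASE_LLD_NAMES)
    return LLDMatrix(
        values=np.column_stack([base, deltas]),
        column_names=names,
        frame_rate_hz=1.0 / _dsp.HOP_S,
    )


# ---------------------------------------------------------------------------
# Pitch LLDs
# ---------------------------------------------------------------------------

def compute_pitch_lld(
    signal: AudioSignal,
    f0_range_hz: tuple[float, float] = (60.0, 500.0),
    window_s: float = 0.05,
) -> tuple[dict[str, np.ndarray], bool]:
    """Framewise pitch-quality contours: F0, local jitter, DDP jitter, local
    shimmer; plus a flag that the signal was entirely unvoiced.

    Pitch periods are located by F0-guided peak picking; per frame, the
    periods within a +/- ``window_s`` neighborhood give local jitter
    (mean |T_i - T_{i-1}| / mean T), DDP jitter (mean second difference of
    periods / mean T) and local shimmer (mean |A_i - A_{i-1}| / mean A).
    A fully unvoiced signal yields all-zero contours.
    """
    from scipy.signal import find_peaks

    fs = signal.sample_rate_hz
    f0, _ = _f0_and_voicing(signal, f0_range_hz, 0.45)
    n_frames = len(f0)
    zeros = {name: np.zeros(n_frames) for name in PITCH_LLD_NAMES}
    voiced = f0[f0 > 0]
    if voiced.size == 0 or n_frames == 0:
        return zeros, True
    f0_med = float(np.median(voiced))
    min_dist = max(2, int(0.7 * fs / f0_med))
    peaks, props = find_peaks(signal.samples, distance=min_dist,
                              height=0.1 * float(np.max(np.abs(signal.samples))))
    if len(peaks) < 4:
        zeros["F0final"] = f0
        return zeros, False
    periods = np.diff(peaks) / fs
    amps = props["peak_heights"][1:]
    period_times = peaks[1:] / fs

    jitter = np.zeros(n_frames)
    ddp = np.zeros(n_frames)
    shimmer = np.zeros(n_frames)
    hop, frame_len_s = _dsp.HOP_S, _dsp.FRAME_S
    for i in range(n_frames):
        if f0[i] == 0:
            continue
        center = i * hop + frame_len_s / 2
        sel = np.abs(period_times - center) <= window_s
        T = periods[sel]
        A = amps[sel]
        if len(T) >= 3:
            jitter[i] = float(np.mean(np.abs(np.diff(T))) / np.mean(T))
            shimmer[i] = float(np.mean(np.abs(np.diff(A))) / np.mean(A))
            if len(T) >= 4:
                ddp[i] = float(np.mean(np.abs(np.diff(T, n=2))) / np.mean(T))
    return (
        {"F0final": f0, "jitterLocal": jitter, "jitterDDP": ddp, "shimmerLocal": shimmer},
        False,
    )


# ---------------------------------------------------------------------------
# Vector assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """The assembled per-utterance feature vector with canonical names."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(self.names) != TOTAL_FEATURES:
            raise ValueError(
                f"feature vector must have {TOTAL_FEATURES} entries, got {len(self.names)}"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def count_pitch_onsets(f0_contour: np.ndarray) -> int:
    """Number of unvoiced-to-voiced transitions (a leading voiced frame
    counts as an onset)."""
    f0 = np.asarray(f0_contour)
    voiced = f0 > 0
    if voiced.size == 0:
        return 0
    starts = voiced & ~np.concatenate(([False], voiced[:-1]))
    return int(np.count_nonzero(starts))


def assemble_feature_vector(
    lld: LLDMatrix,
    pitch_lld: dict[str, np.ndarray],
    f0_contour: np.ndarray,
    duration_s: float,
) -> FeatureVector:
    """Assemble main (68 x 21), pitch (8 x 19) and appended (2) blocks."""
    names: list[str] = []
    values: list[float] = []
    for col in lld.column_names:
        contour = lld.column(col)
        for fn in FUNCTIONAL_NAMES:
            names.append(f"{col}_{fn}")
            values.append(compute_functional(fn, contour))
    if len(names) != MAIN_BLOCK:
        raise ValueError(f"main block assembled {len(names)} features, expected {MAIN_BLOCK}")

    missing = [n for n in PITCH_LLD_NAMES if n not in pitch_lld]
    if missing:
        raise ValueError(f"pitch block missing contours: {missing}")
    pitch_cols: list[tuple[str, np.ndarray]] = []
    for name in PITCH_LLD_NAMES:
        pitch_cols.append((name, np.asarray(pitch_lld[name], dtype=np.float64)))
    for name, contour in list(pitch_cols):
        pitch_cols.append((f"{name}_de", delta_coefficients(contour)))
    start = len(names)
    for name, contour in pitch_cols:
        for fn in REDUCED_FUNCTIONAL_NAMES:
            names.append(f"{name}_{fn}")
            values.append(compute_functional(fn, contour))
    if len(names) - start != PITCH_BLOCK:
        raise ValueError(
            f"pitch block assembled {len(names) - start} features, expected {PITCH_BLOCK}"
        )

    names.append("numPitchOnsets")
    values.append(float(count_pitch_onsets(f0_contour)))
    names.append("durationSec")
    values.append(float(duration_s))
    return FeatureVector(names=tuple(names), values=np.asarray(values))


def extract_features(signal: AudioSignal) -> FeatureVector:
    """End-to-end per-utterance extraction from mono audio."""
    lld = compute_base_lld(signal)
    pitch, _unvoiced = compute_pitch_lld(signal)
    return assemble_feature_vector(lld, pitch, pitch["F0final"], signal.duration_s)
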