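"""Shared short-time analysis primitives: framing, windows, LPC."""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_toeplitz

FRAME_S = 0.025
HOP_S = 0.010
PREEMPHASIS = 0.97


def preemphasize(x: np.ndarray, coeff: float = PREEMPHASIS) -> np.ndarray:
    if len(x) == 0:
        return x
    return np.concatenate(([x[0]], x[1:] - coeff * x[:-1]))


def frame_signal(
    x: np.ndarray,
    sample_rate_hz: float,
    frame_s: float = FRAME_S,
    hop_s: float = HOP_S,
) -> np.ndarray:
    """Slice into overlapping frames (n_frames, frame_len); the tail that
    does not fill a frame is dropped.  At least one frame is returned iff
    len(x) >= frame_len."""
    frame_len = int(round(frame_s * sample_rate_hz))
    hop = int(round(hop_s * sample_rate_hz))
    if len(x) < frame_len:
        return np.empty((0, frame_len))
    n = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def lpc(frame: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method linear prediction coefficients.

    Returns ``a`` with a[0] = 1 such that the prediction error filter is
    A(z) = 1 + a[1] z^-1 + ... + a[order] z^-order.  Falls back to the
    trivial predictor for degenerate (silent / too short) frames.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if len(frame) <= order or not np.any(frame):
        return np.concatenate(([1.0], np.zeros(order)))
    r = np.correlate(frame, frame, mode="full")[len(frame) - 1 : len(frame) + order]
    # tiny ridge keeps the Toeplitz system well-posed for near-silent frames
    r = r.copy()
    r[0] *= 1.0 + 1e-9
    r[0] += 1e-12
    try:
        coeffs = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    except np.linalg.LinAlgError:
        return np.concatenate(([1.0], np.zeros(order)))
    return np.concatenate(([1.0], coeffs))
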