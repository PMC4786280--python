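"""Formant extraction and the vocalic triangle.

Formants are spectral peaks of the voice spectrum, physically the resonances
of the vocal tract: F1 tracks the vertical tongue position, F2 the horizontal
one, F3 nasal-cavity action.  Plotting the five Czech vowels in the (F1, F2)
plane gives the *vocalic triangle*; a correctly articulated vowel occupies a
well-defined vertex.  Children with SLI displace vowels when they occur inside
difficult multisyllabic words, so the screening compares the triangle from
isolated vowels against the triangle from in-word vowels: large per-vowel
displacement and a distorted area flag misarticulation.

Extraction is classic LPC root-finding: pre-emphasis, 25 ms Hamming frames,
order 2 + fs/1000 linear prediction, polynomial roots converted to resonance
frequencies/bandwidths, broad resonances discarded, per-frame candidates
reduced by the median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _dsp
from .audioprep import AudioSignal
from .tasks import VOWELS

__all__ = [
    "FormantSet",
    "VocalicTriangle",
    "TriangleComparison",
    "InsufficientResonancesError",
    "TriangleSchemaError",
    "estimate_f0",
    "extract_formants",
    "build_vocalic_triangle",
    "compare_triangles",
]

#: Resonances broader than this are not treated as formants.
BANDWIDTH_CUTOFF_HZ = 400.0
#: Roots below this frequency are discarded as F0 / DC leakage.
MIN_FORMANT_HZ = 90.0
#: Default per-vowel displacement above which a vowel counts as misplaced.
DEFAULT_MISPLACEMENT_HZ = 100.0


class InsufficientResonancesError(RuntimeError):
    """Too few valid LPC resonances to report the requested formants."""


class TriangleSchemaError(ValueError):
    """Vowel set of a triangle is incomplete or duplicated."""


@dataclass(frozen=True)
class FormantSet:
    """F0 and the first three formants of one vowel realization."""

    F0_hz: float
    F1_hz: float
    F2_hz: float
    F3_hz: float
    vowel: str
    context: str  # "isolated" | "in_word"

    def __post_init__(self) -> None:
        if not (0 < self.F1_hz < self.F2_hz < self.F3_hz):
            raise ValueError(
                f"formants must satisfy 0 < F1 < F2 < F3, got "
                f"({self.F1_hz:.0f}, {self.F2_hz:.0f}, {self.F3_hz:.0f})"
            )


@dataclass(frozen=True)
class VocalicTriangle:
    """Map vowel -> (F1, F2) for the five Czech vowels, in one context."""

    vertices: dict[str, tuple[float, float]]
    context: str

    def __post_init__(self) -> None:
        missing = [v for v in VOWELS if v not in self.vertices]
        extra = [v for v in self.vertices if v not in VOWELS]
        if missing or extra:
            raise TriangleSchemaError(
                f"triangle needs exactly vowels {list(VOWELS)}; "
                f"missing={missing} unexpected={extra}"
            )
        for v, (f1, f2) in self.vertices.items():
            if f1 <= 0 or f2 <= 0:
                raise TriangleSchemaError(f"non-positive formant for vowel {v!r}")

    def area(self) -> float:
        """Shoelace area of the vowel polygon in the (F1, F2) plane, Hz^2."""
        pts = np.array([self.vertices[v] for v in VOWELS])
        x, y = pts[:, 0], pts[:, 1]
        return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


@dataclass(frozen=True)
class TriangleComparison:
    """Per-vowel displacement between two contexts of the same speaker."""

    displacement_hz: dict[str, float]
    misplaced: dict[str, bool]
    area_ratio: float
    threshold_hz: float


def estimate_f0(
    signal: AudioSignal,
    f0_range_hz: tuple[float, float] = (60.0, 500.0),
    voicing_threshold: float = 0.45,
) -> np.ndarray:
    """Framewise autocorrelation F0 estimate; unvoiced frames carry 0.

    A frame is voiced when the normalized autocorrelation peak inside the lag
    range exceeds ``voicing_threshold`` and the frame has non-negligible
    energy.  The default range covers children's voices.
    """
    lo, hi = f0_range_hz
    if not (0 < lo < hi):
        raise ValueError("f0_range_hz must be an increasing positive pair")
    f0, _ = _f0_and_voicing(signal, (lo, hi), voicing_threshold)
    return f0


def _f0_and_voicing(
    signal: AudioSignal,
    f0_range_hz: tuple[float, float],
    voicing_threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared worker: (F0 contour with 0 = unvoiced, unclipped voicing prob)."""
    fs = signal.sample_rate_hz
    frames = _dsp.frame_signal(signal.samples, fs)
    if frames.size == 0:
        return np.zeros(0), np.zeros(0)
    lag_min = max(2, int(np.floor(fs / f0_range_hz[1])))
    lag_max = int(np.ceil(fs / f0_range_hz[0]))
    f0 = np.zeros(len(frames))
    voicing = np.zeros(len(frames))
    energy_floor = 1e-6 * float(np.max(np.mean(np.square(frames), axis=1)) or 1.0)
    for i, frame in enumerate(frames):
        frame = frame - frame.mean()
        e0 = float(np.dot(frame, frame))
        if e0 <= 0 or np.mean(np.square(frame)) < energy_floor:
            continue
        ac = np.correlate(frame, frame, mode="full")[len(frame) - 1 :]
        hi = min(lag_max, len(ac) - 1)
        if hi <= lag_min:
            continue
        seg = ac[lag_min : hi + 1] / e0
        k = int(np.argmax(seg))
        # parabolic interpolation around the peak lag
        lag = lag_min + k
        if 0 < k < len(seg) - 1:
            denom = seg[k - 1] - 2 * seg[k] + seg[k + 1]
            if abs(denom) > 1e-12:
                lag = lag + 0.5 * (seg[k - 1] - seg[k + 1]) / denom
        voicing[i] = max(0.0, float(seg[k]))
        if voicing[i] >= voicing_threshold:
            f0[i] = fs / lag
    return f0, voicing


def extract_formants(
    signal: AudioSignal,
    n_formants: int = 3,
    lpc_order: int | None = None,
    context: str = "isolated",
    vowel: str = "?",
) -> FormantSet:
    """Estimate F0 and the first ``n_formants`` formants of a vowel segment.

    Per frame, roots of the LPC polynomial above the real axis are converted
    to candidate resonances ``f = angle * fs / (2 pi)`` with bandwidth
    ``-fs/pi * ln|r|``; candidates below 90 Hz or broader than 400 Hz are
    discarded; the lowest ``n_formants`` survivors are collected and the
    per-formant median over frames is reported.
    """
    fs = signal.sample_rate_hz
    if lpc_order is None:
        lpc_order = 2 + int(round(fs / 1000.0))
    x = _dsp.preemphasize(signal.samples)
    frames = _dsp.frame_signal(x, fs)
    if len(frames) < 3:
        raise InsufficientResonancesError(
            f"voiced segment too short: {len(frames)} frames (< 3)"
        )
    window = np.hamming(frames.shape[1])
    per_frame: list[np.ndarray] = []
    for frame in frames * window:
        a = _dsp.lpc(frame, lpc_order)
        roots = np.roots(a)
        roots = roots[np.imag(roots) > 0]
        if roots.size == 0:
            continue
        freqs = np.angle(roots) * fs / (2 * np.pi)
        bws = -fs / np.pi * np.log(np.maximum(np.abs(roots), 1e-12))
        ok = (freqs > MIN_FORMANT_HZ) & (bws < BANDWIDTH_CUTOFF_HZ)
        cand = np.sort(freqs[ok])
        if len(cand) >= n_formants:
            per_frame.append(cand[:n_formants])
    if len(per_frame) < 3:
        raise InsufficientResonancesError(
            f"only {len(per_frame)} frames carried >= {n_formants} valid resonances (< 3)"
        )
    formants = np.median(np.vstack(per_frame), axis=0)
    f0_contour = estimate_f0(signal)
    voiced = f0_contour[f0_contour > 0]
    f0 = float(np.median(voiced)) if voiced.size else 0.0
    return FormantSet(
        F0_hz=f0,
        F1_hz=float(formants[0]),
        F2_hz=float(formants[1]),
        F3_hz=float(formants[2]),
        vowel=vowel,
        context=context,
    )


def build_vocalic_triangle(
    formant_sets: list[FormantSet] | dict[str, FormantSet],
    context: str,
) -> VocalicTriangle:
    """Assemble the five-vowel (F1, F2) polygon for one context."""
    if isinstance(formant_sets, dict):
        items = list(formant_sets.items())
    else:
        items = [(fs_.vowel, fs_) for fs_ in formant_sets]
    seen: dict[str, tuple[float, float]] = {}
    for vowel, fset in items:
        if fset.context != context:
            raise TriangleSchemaError(
                f"vowel {vowel!r} has context {fset.context!r}, expected {context!r}"
            )
        if vowel in seen:
            raise TriangleSchemaError(f"duplicate vowel {vowel!r}")
        seen[vowel] = (fset.F1_hz, fset.F2_hz)
    return VocalicTriangle(vertices=seen, context=context)


def compare_triangles(
    isolated: VocalicTriangle,
    in_word: VocalicTriangle,
    threshold_hz: float = DEFAULT_MISPLACEMENT_HZ,
) -> TriangleComparison:
    """Per-vowel (F1, F2) displacement, misplacement flags, and area ratio.

    The two triangles must carry different context tags (the comparison is
    isolated-versus-in-word by construction).
    """
    if isolated.context == in_word.context:
        raise ValueError(
            f"both triangles tagged {isolated.context!r}; compare different contexts"
        )
    disp = {}
    for v in VOWELS:
        a = np.array(isolated.vertices[v])
        b = np.array(in_word.vertices[v])
        disp[v] = float(np.linalg.norm(b - a))
    misplaced = {v: disp[v] > threshold_hz for v in VOWELS}
    iso_area = isolated.area()
    ratio = in_word.area() / iso_area if iso_area > 0 else np.inf
    return TriangleComparison(
        displacement_hz=disp,
        misplaced=misplaced,
        area_ratio=float(ratio),
        threshold_hz=threshold_hz,
    )
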