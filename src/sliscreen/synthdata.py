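"""Synthetic cohorts of child speakers for end-to-end testing of the screen.

Real recordings of children with Specific Language Impairment are access
controlled, so every downstream stage is exercised on generated data that
reproduces the structural properties the analysis relies on:

* a two-group cohort (``control`` / ``case``) with per-case severity grades
  1–3 and repeated task realizations, mirroring the corpus bookkeeping;
* the 13-category speaking-task battery with its 57 target patterns;
* group-dependent phoneme substitution / deletion / insertion rates, which
  drive the penalty-score separation between groups;
* group-dependent formant displacement of vowels *inside* multisyllabic
  words, which drives the vocalic-triangle distortion.

Audio is source–filter synthesis: a band-limited impulse train at F0 through
a cascade of second-order resonators at the requested formants — the simplest
source for which LPC formant recovery is well posed.  It makes no attempt at
naturalistic child voices; consonants are short noise bursts that merely
separate the vowel segments in time.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .audioprep import AudioSignal, write_wav, read_wav
from .tasks import TASK_CATALOGUE, TaskItem, VOWELS, tokenize

__all__ = [
    "VOWEL_FORMANTS_HZ",
    "UtteranceRealization",
    "SpeakerRecord",
    "SynthesisConfig",
    "synthesize_vowel",
    "synthesize_word",
    "corrupt_phonemes",
    "generate_cohort",
    "write_database_tree",
    "read_database_tree",
]

#: Canonical Czech vowel formant targets (F1, F2, F3) in Hz.  Round reference
#: values; real child formants are higher and far more variable, but these
#: give the standard triangle ordering (/i/ lowest F1, /a/ highest F1).
VOWEL_FORMANTS_HZ: dict[str, tuple[float, float, float]] = {
    "a": (850.0, 1400.0, 2600.0),
    "e": (600.0, 1700.0, 2500.0),
    "i": (300.0, 2300.0, 3000.0),
    "o": (500.0, 900.0, 2400.0),
    "u": (350.0, 700.0, 2200.0),
}

#: Substitution alphabet for the error process.
_ALPHABET = tuple("abcdefghijklmnoprstuvz") + ("ch", "ě", "š", "č", "ř", "ž", "ů")


@dataclass
class UtteranceRealization:
    """One realized utterance: what the child was asked to say and what came out."""

    task: TaskItem
    realized_phonemes: tuple[str, ...]
    audio_path: str | None = None
    truth_errors: tuple[int, int, int] | None = None  # (wp, up, mp) actually applied
    audio: AudioSignal | None = None
    segments: list[tuple[str, float, float]] | None = None  # (phoneme, start_s, end_s)

    def __post_init__(self) -> None:
        if self.truth_errors is not None:
            if any(e < 0 for e in self.truth_errors):
                raise ValueError("truth error counts must be nonnegative")


@dataclass
class SpeakerRecord:
    """One child: group membership, optional severity, and task realizations."""

    speaker_id: str
    group: str  # "control" | "case"
    severity: int | None
    age_years: int
    sex: str
    realizations: list[UtteranceRealization] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in ("control", "case"):
            raise ValueError(f"group must be control/case, got {self.group!r}")
        if (self.severity is not None) != (self.group == "case"):
            raise ValueError("severity must be present iff group == 'case'")
        if self.severity is not None and self.severity not in (1, 2, 3):
            raise ValueError("severity grade must be 1, 2 or 3")
        if not 4 <= self.age_years <= 12:
            raise ValueError("age must be within [4, 12] years")


@dataclass(frozen=True)
class SynthesisConfig:
    """Knobs of the cohort generator.

    Error rates are per phoneme.  Cases at severity ``s`` use ``s`` times the
    severity-1 case rates (capped at 1), so grade 3 speakers make roughly
    three times the errors of grade 1 speakers.  ``formant_shift_hz`` is the
    (F1, F2) displacement applied to case vowels inside multisyllabic words;
    controls are never shifted.
    """

    n_controls: int = 20
    n_cases: int = 20
    severity_mix: tuple[float, float, float] = (0.4, 0.35, 0.25)
    control_rates: tuple[float, float, float] = (0.01, 0.005, 0.005)  # sub, del, ins
    case_rates: tuple[float, float, float] = (0.10, 0.05, 0.03)  # severity 1
    formant_shift_hz: tuple[float, float] = (150.0, 150.0)
    speaker_formant_jitter_hz: float = 15.0
    f0_hz: float = 210.0
    f0_jitter_hz: float = 20.0
    sample_rate_hz: int = 16000
    noise_snr_db: float | None = None  # None = noiseless
    vowel_duration_s: float = 0.4
    # isolated vowels, plus multisyllabic material whose vowels jointly cover
    # the whole triangle: "různobarevný" (o,a,e), "pivo" (i,o),
    # "kouzelný měšec" (o,u,e)
    audio_tasks: tuple[tuple[str, int], ...] = (
        ("T1", 1), ("T1", 2), ("T1", 3), ("T1", 4), ("T1", 5),
        ("T7", 1), ("T4", 2), ("T8", 2),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for rates in (self.control_rates, self.case_rates):
            if any(not 0 <= r <= 1 for r in rates):
                raise ValueError("error rates must lie in [0, 1]")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ValueError("severity_mix must sum to 1")
        if self.sample_rate_hz not in (16000, 44100):
            raise ValueError("sample_rate_hz must be 16000 or 44100")

    def rates_for(self, group: str, severity: int | None) -> tuple[float, float, float]:
        if group == "control":
            return self.control_rates
        s = severity or 1
        return tuple(min(1.0, r * s) for r in self.case_rates)  # type: ignore[return-value]


def synthesize_vowel(
    vowel: str,
    formants_hz: tuple[float, float, float],
    f0_hz: float,
    duration_s: float,
    sample_rate_hz: int,
    seed: int = 0,
    noise_snr_db: float | None = None,
    bandwidths_hz: tuple[float, float, float] = (80.0, 100.0, 140.0),
    vibrato: float = 0.05,
    vibrato_hz: float = 5.0,
    aspiration_db: float = -25.0,
) -> AudioSignal:
    """Source–filter synthesis of a steady vowel.

    Excitation is a band-limited impulse train at ``f0_hz`` — harmonics up to
    95% of Nyquist with a −6 dB/oct glottal tilt (amplitude 1/k), a slow
    vibrato (default ±5% at 5 Hz, as in natural phonation) and a low-level
    aspiration-noise floor.  The vibrato and aspiration are part of the
    source model: they sweep the harmonics through the resonances and fill
    the spectrum between them, which keeps LPC formant recovery unbiased
    at child-like fundamental frequencies.  The filter is a cascade of three
    second-order resonators at ``formants_hz``; output is peak normalized to
    0.9 with 5 ms cosine on/off ramps.  Deterministic for a given seed.
    """
    f1, f2, f3 = formants_hz
    nyquist = sample_rate_hz / 2.0
    if not (0 < f1 < f2 < f3 < nyquist):
        raise ValueError(
            f"formants must satisfy 0 < F1 < F2 < F3 < Nyquist ({nyquist:.0f} Hz), "
            f"got ({f1:.0f}, {f2:.0f}, {f3:.0f})"
        )
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if f0_hz <= 0:
        raise ValueError("f0_hz must be positive")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    f0_t = f0_hz * (1.0 + vibrato * np.sin(2 * np.pi * vibrato_hz * t))
    phase = 2 * np.pi * np.cumsum(f0_t) / sample_rate_hz
    n_harm = max(1, int(np.floor(0.95 * nyquist / (f0_hz * (1.0 + abs(vibrato))))))
    k = np.arange(1, n_harm + 1)[:, None]
    x = ((1.0 / k) * np.cos(k * phase[None, :])).sum(axis=0)
    rng = np.random.default_rng(seed)
    x = x + 10.0 ** (aspiration_db / 20.0) * float(np.std(x)) * rng.standard_normal(n)
    for f, bw in zip((f1, f2, f3), bandwidths_hz):
        r = np.exp(-np.pi * bw / sample_rate_hz)
        theta = 2 * np.pi * f / sample_rate_hz
        a = [1.0, -2 * r * np.cos(theta), r * r]
        gain = 1 - 2 * r * np.cos(theta) + r * r  # unity response near DC-free peak
        x = lfilter([gain], a, x)
    if noise_snr_db is not None:
        sig_power = float(np.mean(np.square(x)))
        noise_power = sig_power / 10 ** (noise_snr_db / 10)
        x = x + rng.normal(0.0, np.sqrt(noise_power), size=n)
    ramp = min(int(0.005 * sample_rate_hz), n // 2)
    if ramp > 0:
        env = np.ones(n)
        win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = win
        env[-ramp:] = win[::-1]
        x = x * env
    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x = 0.9 * x / peak
    return AudioSignal(x, float(sample_rate_hz))


def synthesize_word(
    phonemes: tuple[str, ...],
    f0_hz: float,
    sample_rate_hz: int,
    formant_table: dict[str, tuple[float, float, float]] | None = None,
    formant_shift_hz: tuple[float, float] = (0.0, 0.0),
    vowel_duration_s: float = 0.18,
    consonant_duration_s: float = 0.06,
    seed: int = 0,
    noise_snr_db: float | None = None,
) -> tuple[AudioSignal, list[tuple[str, float, float]]]:
    """Concatenative word synthesis with per-phoneme timing.

    Vowels are resonator-synthesized (with the in-word ``formant_shift_hz``
    applied to F1/F2); consonants are low-level noise bursts that only
    delimit the vowels.  Returns the signal plus (phoneme, start_s, end_s)
    segments so in-word vowels can be located without forced alignment.
    """
    table = formant_table or VOWEL_FORMANTS_HZ
    rng = np.random.default_rng(seed)
    pieces: list[np.ndarray] = []
    segments: list[tuple[str, float, float]] = []
    cursor = 0.0
    for ph in phonemes:
        if ph in table:
            f1, f2, f3 = table[ph]
            sig = synthesize_vowel(
                ph,
                (f1 + formant_shift_hz[0], f2 + formant_shift_hz[1], f3),
                f0_hz,
                vowel_duration_s,
                sample_rate_hz,
                seed=seed,
                noise_snr_db=noise_snr_db,
            )
            piece = sig.samples
            dur = vowel_duration_s
        else:
            n = int(round(consonant_duration_s * sample_rate_hz))
            piece = 0.05 * rng.standard_normal(n)
            ramp = max(1, n // 8)
            env = np.ones(n)
            win = np.linspace(0, 1, ramp)
            env[:ramp] = win
            env[-ramp:] = win[::-1]
            piece = piece * env
            dur = consonant_duration_s
        segments.append((ph, cursor, cursor + dur))
        pieces.append(piece)
        cursor += dur
    samples = np.concatenate(pieces) if pieces else np.zeros(0)
    peak = float(np.max(np.abs(samples))) if samples.size else 0.0
    if peak > 0:
        samples = 0.9 * samples / peak
    return AudioSignal(samples, float(sample_rate_hz)), segments


def corrupt_phonemes(
    target: tuple[str, ...] | list[str],
    sub_rate: float,
    del_rate: float,
    ins_rate: float,
    seed: int | np.random.Generator = 0,
) -> tuple[tuple[str, ...], tuple[int, int, int]]:
    """Apply an i.i.d. per-token error process to a target phoneme sequence.

    Order: substitutions first (a token is replaced by a different alphabet
    token), then deletions, then insertions (a random token after a surviving
    token, plus possibly one before the sequence).  Returns the realized
    sequence and the exact ground-truth (wp, up, mp) = (substitutions,
    deletions, insertions) applied.
    """
    target = tuple(target)
    if not target:
        raise ValueError("target sequence must be non-empty")
    for r in (sub_rate, del_rate, ins_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wp = up = mp = 0
    substituted: list[str] = []
    for tok in target:
        if rng.random() < sub_rate:
            choices = [c for c in _ALPHABET if c != tok]
            substituted.append(choices[rng.integers(len(choices))])
            wp += 1
        else:
            substituted.append(tok)
    kept: list[str] = []
    for tok in substituted:
        if rng.random() < del_rate:
            up += 1
        else:
            kept.append(tok)
    realized: list[str] = []
    if rng.random() < ins_rate:
        realized.append(_ALPHABET[rng.integers(len(_ALPHABET))])
        mp += 1
    for tok in kept:
        realized.append(tok)
        if rng.random() < ins_rate:
            realized.append(_ALPHABET[rng.integers(len(_ALPHABET))])
            mp += 1
    return tuple(realized), (wp, up, mp)


def _speaker_rng(seed: int, speaker_id: str) -> np.random.Generator:
    """One stream per speaker keyed by (seed, id): adding speakers to a
    cohort does not reshuffle existing ones."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(speaker_id.encode())])
    )


def generate_cohort(config: SynthesisConfig) -> list[SpeakerRecord]:
    """Generate a full two-group cohort over the task catalogue.

    Every speaker realizes all 57 task patterns through the group/severity
    error process; the tasks in ``config.audio_tasks`` additionally carry
    synthesized audio (isolated vowels, and multisyllabic words whose in-word
    vowels get the case-group formant shift).
    """
    if config.n_controls + config.n_cases < 2:
        raise ValueError("need at least 2 speakers in total")
    if not TASK_CATALOGUE:
        raise ValueError("empty task catalogue")
    audio_keys = set(config.audio_tasks)
    cohort: list[SpeakerRecord] = []
    specs = [("control", f"ctrl_{i+1:03d}") for i in range(config.n_controls)]
    specs += [("case", f"case_{i+1:03d}") for i in range(config.n_cases)]
    for group, sid in specs:
        rng = _speaker_rng(config.seed, sid)
        severity = None
        if group == "case":
            severity = 1 + int(rng.choice(3, p=np.asarray(config.severity_mix)))
        age = int(rng.integers(4, 13))
        sex = "M" if rng.random() < 0.5 else "F"
        f0 = config.f0_hz + float(rng.uniform(-1, 1)) * config.f0_jitter_hz
        # per-speaker vowel table: shared jitter on top of the canonical values
        table = {}
        for v, (f1, f2, f3) in VOWEL_FORMANTS_HZ.items():
            j = config.speaker_formant_jitter_hz
            table[v] = (
                f1 + float(rng.uniform(-j, j)),
                f2 + float(rng.uniform(-j, j)),
                f3,
            )
        shift = config.formant_shift_hz if group == "case" else (0.0, 0.0)
        sub, dele, ins = config.rates_for(group, severity)
        realizations: list[UtteranceRealization] = []
        for task in TASK_CATALOGUE:
            realized, truth = corrupt_phonemes(task.target_phonemes, sub, dele, ins, rng)
            real = UtteranceRealization(task=task, realized_phonemes=realized, truth_errors=truth)
            if (task.task_code, task.pattern_index) in audio_keys:
                aseed = int(rng.integers(2**31 - 1))
                if task.task_code == "T1":
                    vowel = task.target_phonemes[0]
                    sig = synthesize_vowel(
                        vowel, table[vowel], f0, config.vowel_duration_s,
                        config.sample_rate_hz, seed=aseed,
                        noise_snr_db=config.noise_snr_db,
                    )
                    real.audio = sig
                    real.segments = [(vowel, 0.0, config.vowel_duration_s)]
                else:
                    sig, segs = synthesize_word(
                        task.target_phonemes, f0, config.sample_rate_hz,
                        formant_table=table, formant_shift_hz=shift,
                        seed=aseed, noise_snr_db=config.noise_snr_db,
                    )
                    real.audio = sig
                    real.segments = segs
            realizations.append(real)
        cohort.append(
            SpeakerRecord(
                speaker_id=sid, group=group, severity=severity,
                age_years=age, sex=sex, realizations=realizations,
            )
        )
    return cohort


MANIFEST_COLUMNS = [
    "speaker_id", "group", "severity", "age_years", "sex",
    "task_code", "pattern_index", "target", "realized",
    "wp", "up", "mp", "wav_path",
]


def write_database_tree(cohort: list[SpeakerRecord], root: str | Path) -> Path:
    """Write one directory per speaker (WAV files + timing sidecars) plus a
    cohort-level ``manifest.csv`` and its JSON mirror.  Returns the manifest
    path.  Round-trips through :func:`read_database_tree`."""
    root = Path(root)
    try:
        root.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create database root {root}: {exc}") from exc
    rows = []
    for spk in cohort:
        spk_dir = root / spk.speaker_id
        spk_dir.mkdir(exist_ok=True)
        for i, real in enumerate(spk.realizations):
            wav_path = ""
            if real.audio is not None:
                name = f"{real.task.task_code}_{real.task.pattern_index:02d}.wav"
                wav_file = spk_dir / name
                write_wav(real.audio, wav_file)
                real.audio_path = str(wav_file.relative_to(root))
                wav_path = real.audio_path
                if real.segments is not None:
                    sidecar = wav_file.with_suffix(".segments.json")
                    sidecar.write_text(json.dumps(
                        [{"phoneme": p, "start_s": s, "end_s": e}
                         for p, s, e in real.segments], indent=0))
            truth = real.truth_errors or (None, None, None)
            rows.append({
                "speaker_id": spk.speaker_id,
                "group": spk.group,
                "severity": spk.severity if spk.severity is not None else "",
                "age_years": spk.age_years,
                "sex": spk.sex,
                "task_code": real.task.task_code,
                "pattern_index": real.task.pattern_index,
                "target": " ".join(real.task.target_phonemes),
                "realized": " ".join(real.realized_phonemes),
                "wp": truth[0] if truth[0] is not None else "",
                "up": truth[1] if truth[1] is not None else "",
                "mp": truth[2] if truth[2] is not None else "",
                "wav_path": wav_path,
            })
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest = root / "manifest.csv"
    df.to_csv(manifest, index=False)
    (root / "manifest.json").write_text(df.to_json(orient="records", indent=0))
    return manifest


def read_database_tree(root: str | Path, load_audio: bool = False) -> list[SpeakerRecord]:
    """Rebuild a cohort from a database tree written by :func:`write_database_tree`
    (or a user-supplied tree with the same manifest schema)."""
    root = Path(root)
    manifest = root / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv under {root}")
    df = pd.read_csv(manifest, keep_default_na=False)
    cohort: list[SpeakerRecord] = []
    for sid, part in df.groupby("speaker_id", sort=False):
        first = part.iloc[0]
        severity = int(first["severity"]) if str(first["severity"]) != "" else None
        realizations = []
        for _, row in part.iterrows():
            task = TaskItem(
                task_code=row["task_code"],
                orthographic_text=row["target"],
                pattern_index=int(row["pattern_index"]),
                target_phonemes=tuple(str(row["target"]).split()),
            )
            truth = None
            if str(row["wp"]) != "":
                truth = (int(row["wp"]), int(row["up"]), int(row["mp"]))
            realized = tuple(str(row["realized"]).split()) if str(row["realized"]) else ()
            real = UtteranceRealization(
                task=task, realized_phonemes=realized,
                audio_path=row["wav_path"] or None, truth_errors=truth,
            )
            if real.audio_path:
                sidecar = (root / real.audio_path).with_suffix(".segments.json")
                if sidecar.exists():
                    segs = json.loads(sidecar.read_text())
                    real.segments = [(d["phoneme"], d["start_s"], d["end_s"]) for d in segs]
                if load_audio:
                    real.audio = read_wav(root / real.audio_path)
            realizations.append(real)
        cohort.append(SpeakerRecord(
            speaker_id=str(sid), group=first["group"], severity=severity,
            age_years=int(first["age_years"]), sex=first["sex"],
            realizations=realizations,
        ))
    return cohort
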