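import numpy as np
import pytest

from sliscreen.audioprep import AudioSignal
from sliscreen.synthdata import SynthesisConfig, generate_cohort, synthesize_vowel


@pytest.fixture(scope="session")
def vowel_a():
    """Noiseless reference /a/ at 120 Hz, 16 kHz."""
    return synthesize_vowel("a", (850, 1400, 2600), 120, 0.4, 16000, seed=1)


@pytest.fixture(scope="session")
def vowel_i():
    return synthesize_vowel("i", (300, 2300, 3000), 120, 0.4, 16000, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """10+10 speaker cohort without audio (fast; penalty-score material)."""
    cfg = SynthesisConfig(n_controls=10, n_cases=10, seed=42, audio_tasks=())
    return generate_cohort(cfg)


@pytest.fixture
def tone_1khz():
    fs = 16000
    t = np.arange(int(0.5 * fs)) / fs
    return AudioSignal(0.5 * np.sin(2 * np.pi * 1000 * t), fs)
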