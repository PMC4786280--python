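"""Speaking-task catalogue and the grapheme tokenizer shared by all stages.

The screening protocol uses 13 task categories (T1–T11 and T13; there is no
T12) ranging from isolated Czech vowels through multisyllabic words to a full
sentence and a picture description.  Each task carries one or more *patterns*
(target utterances).  Graphemes stand in for phones throughout: the corpus has
no phonetic transcription layer, and the Czech orthography is close enough to
phonemic for error counting, with the single caveat that the digraph "ch" is
one phoneme and is tokenized as one token.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TaskItem",
    "tokenize",
    "TASK_CATALOGUE",
    "TASK_CODES",
    "VOWELS",
    "catalogue_by_code",
]

#: The five Czech vowels of task T1, also the vertices of the vocalic triangle.
VOWELS = ("a", "o", "u", "e", "i")

_WORD_SEPARATORS = " \t\n-–—"


def tokenize(text: str) -> list[str]:
    """Tokenize an orthographic string into phoneme-standing graphemes.

    Lowercases, drops separators and punctuation, and treats the Czech
    digraph "ch" as a single token.  Diacritics are preserved (``ě``, ``š``,
    ``ů`` ... are distinct phonemes).

    >>> tokenize("Chleba")
    ['ch', 'l', 'e', 'b', 'a']
    """
    text = text.lower()
    tokens: list[str] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c in _WORD_SEPARATORS or not c.isalpha():
            i += 1
            continue
        if c == "c" and i + 1 < len(text) and text[i + 1] == "h":
            tokens.append("ch")
            i += 2
        else:
            tokens.append(c)
            i += 1
    return tokens


@dataclass(frozen=True)
class TaskItem:
    """One target utterance of the speaking-task battery.

    Parameters
    ----------
    task_code:
        One of ``T1`` ... ``T11``, ``T13``.
    orthographic_text:
        The Czech target text as presented to the child.
    pattern_index:
        1-based index of the pattern within its task category.
    target_phonemes:
        Token sequence; derived from the text by :func:`tokenize` when not
        given explicitly.
    """

    task_code: str
    orthographic_text: str
    pattern_index: int
    target_phonemes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.task_code not in TASK_CODES:
            raise ValueError(
                f"unknown task code {self.task_code!r}; expected one of {sorted(TASK_CODES)}"
            )
        if self.pattern_index < 1:
            raise ValueError("pattern_index must be >= 1")
        if not self.target_phonemes:
            object.__setattr__(
                self, "target_phonemes", tuple(tokenize(self.orthographic_text))
            )
        if not self.target_phonemes:
            raise ValueError(f"task {self.task_code} pattern {self.pattern_index}: empty target")


_CATALOGUE_SPEC: dict[str, list[str]] = {
    # T1 isolated vowels
    "T1": ["a", "o", "u", "e", "i"],
    # T2 isolated consonants ("ch" is one phoneme)
    "T2": ["m", "b", "t", "d", "r", "l", "k", "g", "h", "ch"],
    # T3 syllables
    "T3": ["pe", "la", "vla", "pro", "bě", "nos", "ber", "krk", "prst"],
    # T4 two-syllable words
    "T4": ["kolo", "pivo", "sokol", "papír", "trdlo"],
    # T5 three-syllable words
    "T5": ["dědeček", "pohádka", "pokémon", "květina"],
    # T6 four-syllable words
    "T6": ["motovidlo", "televize", "popelnice"],
    # T7 difficult words
    "T7": ["různobarevný", "mateřídouška"],
    # T8 geminate (multi-word) expressions
    "T8": ["pohádková víla", "kouzelný měšec", "čarotvorný hrnec"],
    # T9 accreting word ranges
    "T9": [
        "voda",
        "živá voda",
        "živá a mrtvá voda",
        "pramen s živou a mrtvou vodou",
    ],
    # T10 sentence
    "T10": ["Když šla červená Karkulka k babičce, potkala zlého vlka."],
    # T11 auditory-differentiation minimal pairs (first member is the target)
    "T11": [
        "pes", "ten", "kůl", "hrát", "ječí",
        "ble", "kloč", "kvěš", "šný", "vošl",
    ],
    # T13 picture description, generated as a fixed sentence
    "T13": ["Podívej se na směšného klauna."],
}

#: Minimal-pair partners for the auditory-differentiation task (T11); each
#: differs from its target in exactly one phoneme.
MINIMAL_PAIRS: dict[str, str] = {
    "pes": "nes",
    "ten": "den",
    "kůl": "vůl",
    "hrát": "brát",
    "ječí": "ježí",
    "ble": "ple",
    "kloč": "kloč",
    "kvěš": "kveš",
    "šný": "šní",
    "vošl": "vočl",
}

TASK_CODES = frozenset(_CATALOGUE_SPEC)

TASK_CATALOGUE: tuple[TaskItem, ...] = tuple(
    TaskItem(code, text, idx)
    for code, texts in _CATALOGUE_SPEC.items()
    for idx, text in enumerate(texts, start=1)
)

#: Canonical ordering of the 12 task categories used for per-task vectors.
TASK_ORDER: tuple[str, ...] = (
    "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T13",
)


def catalogue_by_code(code: str) -> list[TaskItem]:
    """Return the patterns of one task category, in pattern order."""
    if code not in TASK_CODES:
        raise ValueError(f"unknown task code {code!r}")
    return [t for t in TASK_CATALOGUE if t.task_code == code]
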