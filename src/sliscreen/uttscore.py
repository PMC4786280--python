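"""Utterance tests: phoneme confusion matrix and the penalty score.

Each target utterance is compared with the child's realization through a
global alignment over an (m+1) x (n+1) edit array (m target phonemes, n
realized phonemes; unit costs for substitution, deletion and insertion,
zero for a match).  From the minimal-cost alignment three error counts are
read off:

* ``wp`` — wrong phonemes (substitutions),
* ``up`` — unspoken phonemes (target phonemes with no realized counterpart;
  deletions),
* ``mp`` — missing-alignment phonemes (realized phonemes with no target
  counterpart; insertions),

and the penalty score is their sum ``PS = wp + up + mp``, the total error
count of the utterance.  PS always equals the unit-cost Levenshtein distance
between the two sequences; the (wp, up, mp) split depends on the tie-break
among equal-cost alignments, which is fixed here (prefer substitution over
deletion over insertion when backtracking left-to-right) so the decomposition
is deterministic.

Unspoken-vs-missing mapping: prose descriptions of the two absence counts do
not pin down which is which; this module maps "unspoken" to deletions and
"missing" to insertions.  The mapping lives entirely in
:func:`penalty_score` and can be flipped there if a corpus convention says
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import SpeakerRecord
from .tasks import TASK_ORDER, tokenize

__all__ = [
    "AlignmentMatrix",
    "PenaltyScore",
    "align_phonemes",
    "penalty_score",
    "score_pair",
    "speaker_error_profile",
    "cohort_error_table",
]

MATCH, SUB, DEL, INS = "match", "sub", "del", "ins"


@dataclass(frozen=True)
class AlignmentMatrix:
    """Edit array over a (target, realized) pair plus one backtracked path.

    ``ops`` lists the alignment operations in left-to-right order; ``cost``
    is the minimal total edit cost (= the distance).
    """

    target: tuple[str, ...]
    realized: tuple[str, ...]
    cost_matrix: np.ndarray  # (m+1, n+1) minimal edit costs
    ops: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.target)

    @property
    def n(self) -> int:
        return len(self.realized)

    @property
    def cost(self) -> int:
        return int(self.cost_matrix[-1, -1])


@dataclass(frozen=True)
class PenaltyScore:
    """Error decomposition of one utterance; ``PS = wp + up + mp``."""

    wp: int
    up: int
    mp: int

    def __post_init__(self) -> None:
        if min(self.wp, self.up, self.mp) < 0:
            raise ValueError("error counts must be nonnegative")

    @property
    def PS(self) -> int:
        return self.wp + self.up + self.mp


def align_phonemes(
    target: tuple[str, ...] | list[str] | str,
    realized: tuple[str, ...] | list[str] | str,
) -> AlignmentMatrix:
    """Minimal-cost global alignment of two phoneme sequences.

    Strings are tokenized with the shared tokenizer; sequences are used as
    given.  Empty sequences are legal.  Backtracking prefers substitution
    over deletion over insertion among equal-cost predecessors, making the
    operation sequence (and hence the wp/up/mp split) deterministic.
    """
    tgt = tuple(tokenize(target) if isinstance(target, str) else target)
    rea = tuple(tokenize(realized) if isinstance(realized, str) else realized)
    m, n = len(tgt), len(rea)
    d = np.zeros((m + 1, n + 1), dtype=np.int64)
    d[:, 0] = np.arange(m + 1)
    d[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub_cost = d[i - 1, j - 1] + (tgt[i - 1] != rea[j - 1])
            d[i, j] = min(sub_cost, d[i - 1, j] + 1, d[i, j - 1] + 1)
    ops: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            step = d[i - 1, j - 1] + (tgt[i - 1] != rea[j - 1])
            if step == d[i, j]:
                ops.append(MATCH if tgt[i - 1] == rea[j - 1] else SUB)
                i, j = i - 1, j - 1
                continue
        if i > 0 and d[i - 1, j] + 1 == d[i, j]:
            ops.append(DEL)
            i -= 1
            continue
        ops.append(INS)
        j -= 1
    return AlignmentMatrix(target=tgt, realized=rea, cost_matrix=d, ops=tuple(reversed(ops)))


def penalty_score(alignment: AlignmentMatrix) -> PenaltyScore:
    """Read (wp, up, mp) off an alignment.  wp = substitutions, up =
    deletions ("unspoken"), mp = insertions ("missing")."""
    ops = alignment.ops
    return PenaltyScore(
        wp=ops.count(SUB),
        up=ops.count(DEL),
        mp=ops.count(INS),
    )


def score_pair(target, realized) -> PenaltyScore:
    """Convenience: align then score."""
    return penalty_score(align_phonemes(target, realized))


def speaker_error_profile(speaker: SpeakerRecord) -> tuple[dict[str, int], int]:
    """Per-task penalty-score vector and the speaker's total error count.

    Returns a 12-component dict keyed by task category (T1–T11, T13) whose
    values sum exactly to the total.
    """
    if not speaker.realizations:
        raise ValueError(f"speaker {speaker.speaker_id} has no realizations")
    profile = {code: 0 for code in TASK_ORDER}
    for real in speaker.realizations:
        ps = score_pair(real.task.target_phonemes, real.realized_phonemes)
        profile[real.task.task_code] += ps.PS
    return profile, sum(profile.values())


def cohort_error_table(cohort: list[SpeakerRecord]) -> pd.DataFrame:
    """Per-speaker error profiles as a tidy table (one row per speaker,
    task columns plus ``total_PS``, group and severity)."""
    rows = []
    for spk in cohort:
        profile, total = speaker_error_profile(spk)
        row = {"speaker_id": spk.speaker_id, "group": spk.group,
               "severity": spk.severity if spk.severity is not None else ""}
        row.update(profile)
        row["total_PS"] = total
        rows.append(row)
    return pd.DataFrame(rows)
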