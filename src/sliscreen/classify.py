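"""Group classification of speakers: threshold boxes, supervised SOMs, and
Spearman-selected feature voting.

Four classifiers operate on the per-speaker penalty-score task vector:

* **HM** ("hand-made") — per-group, per-feature minimum/maximum boxes fitted
  on training data; a sample inside exactly one group's box takes that group,
  otherwise it is resolved by its margin to the box boundaries and flagged.
* **ANN random / min-max / mean** — a supervised self-organizing map whose
  codebook is initialized with small random values, with the group min/max
  limit vectors, or with the group mean vectors.

A fifth classifier works on the large acoustic feature set: per word, the 30
features with the highest absolute Spearman rank correlation against the
group label are selected on training data; each selected feature of the
evaluated speaker is assigned to the group whose training median is nearer,
and the speaker goes to the group with the larger total tally.

Evaluation is leave-one-speaker-out throughout (resubstitution is available
for comparison).  Ties everywhere resolve to "case": a screening instrument
should err toward sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .som import SOMModel, som_classify, som_train

__all__ = [
    "GroupLimits",
    "ClassificationResult",
    "fit_hm_limits",
    "hm_classify",
    "spearman_select",
    "vote_classify",
    "evaluate_loocv",
    "evaluate_voting_loocv",
    "TABLE_METHODS",
]

GROUPS = ("control", "case")
#: The four threshold/SOM screening methods, in canonical report order.
TABLE_METHODS = ("HM", "ANN-random", "ANN-minmax", "ANN-mean")


# ---------------------------------------------------------------------------
# HM: min-max threshold boxes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupLimits:
    """Per-group, per-feature observed [min, max] boxes."""

    mins: dict[str, np.ndarray]
    maxs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for g in self.mins:
            if np.any(self.mins[g] > self.maxs[g]):
                raise ValueError(f"group {g!r}: min > max")


def fit_hm_limits(X: np.ndarray, labels: np.ndarray | list[str]) -> GroupLimits:
    """Per-group feature minima and maxima from labeled training vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    labels = np.asarray(labels)
    mins, maxs = {}, {}
    for g in GROUPS:
        rows = X[labels == g]
        if rows.size == 0:
            raise ValueError(f"cannot fit limits: no training samples for group {g!r}")
        mins[g] = rows.min(axis=0)
        maxs[g] = rows.max(axis=0)
    return GroupLimits(mins=mins, maxs=maxs)


def _box_margin(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    """Signed margin to a box: positive inside (distance to the nearest
    face), negative outside (Euclidean distance to the box)."""
    below = lo - x
    above = x - hi
    outside = np.maximum(np.maximum(below, above), 0.0)
    if np.any(outside > 0):
        return -float(np.linalg.norm(outside))
    return float(np.min(np.minimum(x - lo, hi - x)))


def hm_classify(x: np.ndarray, limits: GroupLimits) -> tuple[str, bool]:
    """Classify by box membership; returns (group, flagged).

    Inside exactly one box: that group, unflagged.  Inside both or neither:
    the group with the larger signed boundary margin (deeper inside, or
    nearer to its box), flagged; exact ties resolve to "case".
    """
    x = np.asarray(x, dtype=np.float64)
    margins = {g: _box_margin(x, limits.mins[g], limits.maxs[g]) for g in GROUPS}
    inside = [g for g in GROUPS if margins[g] >= 0]
    if len(inside) == 1:
        return inside[0], False
    if margins["case"] >= margins["control"]:
        return "case", True
    return "control", True


# ---------------------------------------------------------------------------
# Spearman feature selection
# ---------------------------------------------------------------------------

def spearman_select(
    features: pd.DataFrame,
    labels: np.ndarray | list[str],
    k: int = 30,
) -> tuple[list[str], pd.Series]:
    """Top-``k`` feature names by |Spearman rho| against the group label.

    The label is encoded 0/1 (control/case); a constant feature gets rho = 0
    rather than NaN.  Ties in |rho| break by feature name so the selection is
    deterministic.  Returns (selected names, the full rho series).
    """
    labels = np.asarray(labels)
    if len(features) < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    y = (labels == "case").astype(np.float64)
    if y.min() == y.max():
        raise ValueError("both groups must be present")
    X = features.to_numpy(dtype=np.float64)
    rx = rankdata(X, axis=0)
    ry = rankdata(y)
    rx_c = rx - rx.mean(axis=0)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=0) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rx_c * ry_c[:, None]).sum(axis=0) / denom, 0.0)
    rho_s = pd.Series(rho, index=features.columns, name="spearman_rho")
    order = sorted(features.columns, key=lambda name: (-abs(rho_s[name]), name))
    return list(order[:k]), rho_s


# ---------------------------------------------------------------------------
# Coefficient voting over selected features
# ---------------------------------------------------------------------------

def vote_classify(
    speaker_features: dict[str, pd.Series],
    selected: dict[str, list[str]],
    references: dict[str, pd.DataFrame],
) -> tuple[str, dict[str, int]]:
    """Vote a speaker into a group over words and selected features.

    For every word and every selected feature, the speaker's value is
    assigned to the group whose training reference (per-feature group median)
    is nearer; equidistant values go to "case".  The speaker is classified to
    the group with the larger total tally (tie: "case").

    Parameters
    ----------
    speaker_features:
        word -> feature Series for the evaluated speaker.
    selected:
        word -> selected feature names (fitted without this speaker).
    references:
        word -> DataFrame with rows "control"/"case" of per-feature medians.
    """
    if not any(selected.values()):
        raise ValueError("no selected features to vote with")
    tally = {g: 0 for g in GROUPS}
    for word, names in selected.items():
        feats = speaker_features[word]
        ref = references[word]
        for name in names:
            d_ctrl = abs(float(feats[name]) - float(ref.loc["control", name]))
            d_case = abs(float(feats[name]) - float(ref.loc["case", name]))
            tally["case" if d_case <= d_ctrl else "control"] += 1
    predicted = "case" if tally["case"] >= tally["control"] else "control"
    return predicted, tally


# ---------------------------------------------------------------------------
# Evaluation drivers
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    """Per-speaker predictions and the aggregate success rate of one method."""

    method: str
    speaker_ids: list[str]
    predicted: list[str]
    actual: list[str]
    votes: list[dict[str, int]] = field(default_factory=list)
    flagged: list[bool] = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        correct = sum(p == a for p, a in zip(self.predicted, self.actual))
        return 100.0 * correct / len(self.actual) if self.actual else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "speaker_id": self.speaker_ids,
            "method": self.method,
            "predicted": self.predicted,
            "actual": self.actual,
        }
        if self.votes:
            rows["votes_control"] = [v.get("control", 0) for v in self.votes]
            rows["votes_case"] = [v.get("case", 0) for v in self.votes]
        return pd.DataFrame(rows)


def _fit_predict(
    method: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    seed: int,
    som_kwargs: dict,
) -> tuple[str, bool]:
    if method == "HM":
        limits = fit_hm_limits(X_train, y_train)
        return hm_classify(x_test, limits)
    scheme = {"ANN-random": "random", "ANN-minmax": "minmax", "ANN-mean": "mean"}.get(method)
    if scheme is None:
        raise ValueError(f"unknown method {method!r}; expected one of {TABLE_METHODS}")
    model = som_train(X_train, y_train, init_scheme=scheme, seed=seed, **som_kwargs)
    return som_classify(x_test, model), False


def evaluate_loocv(
    X: np.ndarray,
    labels: np.ndarray | list[str],
    method: str,
    speaker_ids: list[str] | None = None,
    seed: int = 0,
    resubstitution: bool = False,
    **som_kwargs,
) -> ClassificationResult:
    """Leave-one-speaker-out evaluation of one Table-method classifier.

    ``X`` holds one feature vector per speaker (the 12-component per-task
    penalty vector by default usage; any vector works).  With
    ``resubstitution=True`` the model is fitted once on everyone and applied
    to everyone.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    labels = np.asarray(labels)
    n = len(labels)
    for g in GROUPS:
        if np.count_nonzero(labels == g) < (1 if resubstitution else 2):
            raise ValueError(f"degenerate cohort: too few speakers in group {g!r}")
    ids = speaker_ids if speaker_ids is not None else [f"s{i}" for i in range(n)]
    predicted, flagged = [], []
    if resubstitution:
        if method == "HM":
            limits = fit_hm_limits(X, labels)
            for i in range(n):
                p, f = hm_classify(X[i], limits)
                predicted.append(p)
                flagged.append(f)
        else:
            scheme = {"ANN-random": "random", "ANN-minmax": "minmax",
                      "ANN-mean": "mean"}[method]
            model = som_train(X, labels, init_scheme=scheme, seed=seed, **som_kwargs)
            for i in range(n):
                predicted.append(som_classify(X[i], model))
                flagged.append(False)
    else:
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[:] = True
            mask[i] = False
            p, f = _fit_predict(method, X[mask], labels[mask], X[i], seed, som_kwargs)
            predicted.append(p)
            flagged.append(f)
    return ClassificationResult(
        method=method,
        speaker_ids=list(ids),
        predicted=predicted,
        actual=list(labels),
        flagged=flagged,
    )


def evaluate_voting_loocv(
    word_features: dict[str, pd.DataFrame],
    labels: np.ndarray | list[str],
    k: int = 30,
    pooled: bool = False,
) -> ClassificationResult:
    """Leave-one-speaker-out evaluation of the Spearman-voting classifier.

    ``word_features`` maps each word to a (speakers x features) frame with a
    shared index of speaker ids.  Selection and group medians are refitted
    for every fold on the remaining speakers only.  With ``pooled=True`` one
    selection is made on the concatenation of all words instead of per word.
    """
    labels = np.asarray(labels)
    words = list(word_features)
    if not words:
        raise ValueError("no word feature tables given")
    index = word_features[words[0]].index
    n = len(index)
    predicted, votes = [], []
    for i in range(n):
        train_idx = np.arange(n) != i
        y_train = labels[train_idx]
        selected: dict[str, list[str]] = {}
        references: dict[str, pd.DataFrame] = {}
        if pooled:
            stacked = pd.concat(
                [word_features[w].iloc[train_idx] for w in words], axis=0
            )
            stacked_labels = np.concatenate([y_train for _ in words])
            names, _ = spearman_select(stacked, stacked_labels, k)
            for w in words:
                selected[w] = names
        else:
            for w in words:
                names, _ = spearman_select(word_features[w].iloc[train_idx], y_train, k)
                selected[w] = names
        for w in words:
            train = word_features[w].iloc[train_idx]
            references[w] = pd.DataFrame(
                {
                    "control": train[y_train == "control"].median(axis=0),
                    "case": train[y_train == "case"].median(axis=0),
                }
            ).T
        spk = {w: word_features[w].iloc[i] for w in words}
        p, tally = vote_classify(spk, selected, references)
        predicted.append(p)
        votes.append(tally)
    return ClassificationResult(
        method="voting",
        speaker_ids=[str(s) for s in index],
        predicted=predicted,
        actual=list(labels),
        votes=votes,
    )
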