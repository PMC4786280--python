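"""End-to-end orchestration: cohort (synthetic or on-disk) to screening report.

Stage order mirrors the analysis protocol: cohort synthesis → recording
unification → formant/vocalic-triangle analysis + utterance penalty scoring +
acoustic feature extraction → classification.  Every stage writes a
self-describing CSV (schema version, config hash and seed in a leading
comment line) under its own name in the output directory, and every stage can
be re-run individually from the previous stage's files.  A single seed makes
the entire run reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustic_features as af
from . import audioprep, formantlab, uttscore
from .classify import TABLE_METHODS, evaluate_loocv, evaluate_voting_loocv
from .synthdata import (
    SpeakerRecord,
    SynthesisConfig,
    generate_cohort,
    read_database_tree,
    write_database_tree,
)
from .tasks import VOWELS

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "StageError"]

log = logging.getLogger("sliscreen")

SCHEMA_VERSION = 1
#: Reported alpha of the study protocol; metadata only — no per-stage test
#: is prescribed.
SIGNIFICANCE_ALPHA = 0.001


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, record: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on record {record!r}: {cause}")
        self.stage = stage
        self.record = record
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full run."""

    out_dir: str = "sliscreen_out"
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    misplacement_threshold_hz: float = 100.0
    som_grid: tuple[int, int] = (8, 8)
    som_epochs: int = 200
    n_selected_features: int = 30
    pooled_selection: bool = False
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "synthesis" in d and isinstance(d["synthesis"], dict):
            syn_known = {f.name for f in dataclasses.fields(SynthesisConfig)}
            syn_unknown = set(d["synthesis"]) - syn_known
            if syn_unknown:
                raise ValueError(f"unknown synthesis keys: {sorted(syn_unknown)}")
            sd = dict(d["synthesis"])
            for key in ("severity_mix", "control_rates", "case_rates",
                        "formant_shift_hz"):
                if key in sd and isinstance(sd[key], list):
                    sd[key] = tuple(sd[key])
            if "audio_tasks" in sd:
                sd["audio_tasks"] = tuple((t, int(i)) for t, i in sd["audio_tasks"])
            d["synthesis"] = SynthesisConfig(**sd)
        if "som_grid" in d and isinstance(d["som_grid"], list):
            d["som_grid"] = tuple(d["som_grid"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location and plot
        switches excluded, so identical analyses hash identically)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("make_plots", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    header = (
        f"# sliscreen schema_version={SCHEMA_VERSION} "
        f"config_hash={config.config_hash()} seed={config.seed} "
        f"alpha={SIGNIFICANCE_ALPHA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_stage_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", keep_default_na=False)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_synth(config: PipelineConfig, out: Path) -> list[SpeakerRecord]:
    cohort = generate_cohort(config.synthesis)
    write_database_tree(cohort, out / "db")
    log.info("synth: %d speakers, %d realizations",
             len(cohort), sum(len(s.realizations) for s in cohort))
    return cohort


def stage_prep(cohort: list[SpeakerRecord], config: PipelineConfig) -> None:
    """Unify every attached recording in place: mono, 16 kHz, -23 dBFS RMS.

    Trimming is skipped here because synthetic recordings carry no padding
    and the in-word vowel segments are located by manifest timing, which
    trimming would invalidate.
    """
    for spk in cohort:
        for real in spk.realizations:
            if real.audio is None:
                continue
            try:
                sig = audioprep.to_mono(real.audio)
                sig = audioprep.resample(sig, audioprep.CANONICAL_RATE_HZ)
                sig = audioprep.normalize_level(sig)
                real.audio = sig
            except Exception as exc:
                raise StageError("prep", f"{spk.speaker_id}/{real.task.task_code}", exc)


def stage_formants(
    cohort: list[SpeakerRecord], config: PipelineConfig, out: Path
) -> pd.DataFrame:
    """Per speaker: isolated vs in-word vocalic triangles and their comparison."""
    rows = []
    for spk in cohort:
        try:
            isolated: dict[str, formantlab.FormantSet] = {}
            in_word: dict[str, formantlab.FormantSet] = {}
            for real in spk.realizations:
                if real.audio is None or real.segments is None:
                    continue
                if real.task.task_code == "T1":
                    vowel = real.task.target_phonemes[0]
                    isolated[vowel] = formantlab.extract_formants(
                        real.audio, context="isolated", vowel=vowel)
                else:
                    fs = real.audio.sample_rate_hz
                    for ph, start, end in real.segments:
                        if ph not in VOWELS or ph in in_word:
                            continue
                        dur = end - start
                        lo = int((start + 0.2 * dur) * fs)
                        hi = int((end - 0.2 * dur) * fs)
                        seg = audioprep.AudioSignal(real.audio.samples[lo:hi], fs)
                        in_word[ph] = formantlab.extract_formants(
                            seg, context="in_word", vowel=ph)
            if len(isolated) < 5 or len(in_word) < 5:
                continue
            tri_iso = formantlab.build_vocalic_triangle(isolated, "isolated")
            tri_word = formantlab.build_vocalic_triangle(in_word, "in_word")
            cmp_ = formantlab.compare_triangles(
                tri_iso, tri_word, config.misplacement_threshold_hz)
            row = {"speaker_id": spk.speaker_id, "group": spk.group}
            for v in VOWELS:
                row[f"disp_{v}_hz"] = round(cmp_.displacement_hz[v], 3)
                row[f"misplaced_{v}"] = cmp_.misplaced[v]
                row[f"iso_F1_{v}"] = round(tri_iso.vertices[v][0], 3)
                row[f"iso_F2_{v}"] = round(tri_iso.vertices[v][1], 3)
                row[f"word_F1_{v}"] = round(tri_word.vertices[v][0], 3)
                row[f"word_F2_{v}"] = round(tri_word.vertices[v][1], 3)
            row["area_ratio"] = round(cmp_.area_ratio, 6)
            row["n_misplaced"] = sum(cmp_.misplaced.values())
            rows.append(row)
        except (formantlab.InsufficientResonancesError, formantlab.TriangleSchemaError):
            log.warning("formants: skipping %s (insufficient vowel coverage)", spk.speaker_id)
        except Exception as exc:
            raise StageError("formants", spk.speaker_id, exc)
    df = pd.DataFrame(rows)
    _write_csv(df, out / "formants.csv", config)
    return df


def stage_score(
    cohort: list[SpeakerRecord], config: PipelineConfig, out: Path
) -> pd.DataFrame:
    try:
        df = uttscore.cohort_error_table(cohort)
    except Exception as exc:
        raise StageError("score", "cohort", exc)
    _write_csv(df, out / "penalty_scores.csv", config)
    return df


def stage_features(
    cohort: list[SpeakerRecord], config: PipelineConfig, out: Path
) -> pd.DataFrame:
    rows = []
    names: tuple[str, ...] | None = None
    for spk in cohort:
        for real in spk.realizations:
            if real.audio is None:
                continue
            try:
                vec = af.extract_features(real.audio)
            except Exception as exc:
                rid = f"{spk.speaker_id}/{real.task.task_code}.{real.task.pattern_index}"
                raise StageError("features", rid, exc)
            names = vec.names
            row = {
                "speaker_id": spk.speaker_id,
                "group": spk.group,
                "task_code": real.task.task_code,
                "pattern_index": real.task.pattern_index,
            }
            row.update({n: v for n, v in zip(vec.names, np.round(vec.values, 9))})
            rows.append(row)
    df = pd.DataFrame(rows)
    _write_csv(df, out / "features.csv", config)
    if names is not None:
        schema = {
            "total": af.TOTAL_FEATURES,
            "main_block": af.MAIN_BLOCK,
            "pitch_block": af.PITCH_BLOCK,
            "appended": af.APPENDED,
            "names": list(names),
        }
        (out / "features.schema.json").write_text(json.dumps(schema, indent=0))
    return df


def stage_classify(
    score_df: pd.DataFrame,
    features_df: pd.DataFrame,
    config: PipelineConfig,
    out: Path,
) -> pd.DataFrame:
    from .tasks import TASK_ORDER

    labels = score_df["group"].to_numpy()
    if len(set(labels)) < 2:
        raise StageError("classify", "cohort",
                         ValueError("single-group cohort: classification needs both groups"))
    X = score_df[list(TASK_ORDER)].to_numpy(dtype=float)
    ids = score_df["speaker_id"].tolist()
    summary_rows = []
    pred_frames = []
    for method in TABLE_METHODS:
        res = evaluate_loocv(
            X, labels, method, speaker_ids=ids, seed=config.seed,
            grid=config.som_grid, epochs=config.som_epochs,
        )
        summary_rows.append({"method": method, "success_rate_pct": round(res.success_rate, 2)})
        pred_frames.append(res.to_frame())
    if len(features_df):
        word_features: dict[str, pd.DataFrame] = {}
        feature_cols = [c for c in features_df.columns
                        if c not in ("speaker_id", "group", "task_code", "pattern_index")]
        for (code, idx), part in features_df.groupby(["task_code", "pattern_index"]):
            part = part.set_index("speaker_id")
            if len(part) == len(ids):
                word_features[f"{code}.{idx}"] = part.loc[ids, feature_cols].astype(float)
        if word_features:
            res = evaluate_voting_loocv(
                word_features, labels, k=config.n_selected_features,
                pooled=config.pooled_selection,
            )
            summary_rows.append({"method": "voting",
                                 "success_rate_pct": round(res.success_rate, 2)})
            pred_frames.append(res.to_frame())
    summary = pd.DataFrame(summary_rows)
    _write_csv(summary, out / "summary.csv", config)
    _write_csv(pd.concat(pred_frames, ignore_index=True), out / "predictions.csv", config)
    return summary


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages; returns the stage tables keyed by stage name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    cohort = stage_synth(config, out)
    stage_prep(cohort, config)
    formants_df = stage_formants(cohort, config, out)
    score_df = stage_score(cohort, config, out)
    features_df = stage_features(cohort, config, out)
    outputs = {"formants": formants_df, "scores": score_df, "features": features_df}
    try:
        outputs["summary"] = stage_classify(score_df, features_df, config, out)
    except StageError as exc:
        if isinstance(exc.cause, ValueError) and "single-group" in str(exc.cause):
            log.warning("classify: %s; earlier stage outputs kept", exc.cause)
        else:
            raise
    run_log = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "alpha": SIGNIFICANCE_ALPHA,
        "n_speakers": len(cohort),
        "elapsed_s": round(time.time() - t0, 2),
        "stages": sorted(outputs),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    make_report(out, plots=config.make_plots)
    return outputs


def make_report(out_dir: str | Path, plots: bool = False) -> Path:
    """Render a human-readable summary from saved stage CSVs.

    Pure function of the files on disk: regenerating from the same CSVs gives
    the same report.  Missing stages are listed as absent.
    """
    out = Path(out_dir)
    lines = ["sliscreen run report", "=" * 40]
    stage_files = {
        "formants": "formants.csv",
        "penalty scores": "penalty_scores.csv",
        "features": "features.csv",
        "summary": "summary.csv",
        "predictions": "predictions.csv",
    }
    tables: dict[str, pd.DataFrame] = {}
    for stage, fname in stage_files.items():
        path = out / fname
        if not path.exists():
            lines.append(f"[{stage}] absent")
            continue
        df = read_stage_csv(path)
        tables[stage] = df
        lines.append(f"[{stage}] {len(df)} rows from {fname}")
    if "summary" in tables and len(tables["summary"]):
        lines.append("")
        lines.append("Classification success rates (leave-one-speaker-out):")
        for _, row in tables["summary"].iterrows():
            lines.append(f"  {row['method']:<12} {row['success_rate_pct']:>7}%")
    if "penalty scores" in tables and len(tables["penalty scores"]):
        df = tables["penalty scores"]
        lines.append("")
        lines.append("Penalty-score totals by group:")
        for g, part in df.groupby("group"):
            tot = part["total_PS"].astype(float)
            lines.append(f"  {g:<8} mean PS {tot.mean():8.2f}  (n={len(part)})")
    report = out / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    if plots:
        _make_plots(tables, out)
    return report


def _make_plots(tables: dict[str, pd.DataFrame], out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "penalty scores" in tables and len(tables["penalty scores"]):
        df = tables["penalty scores"].sort_values(["group", "speaker_id"])
        fig, ax = plt.subplots(figsize=(8, 3))
        colors = df["group"].map({"case": "tab:blue", "control": "tab:orange"})
        ax.bar(df["speaker_id"], df["total_PS"].astype(float), color=colors)
        ax.set_ylabel("number of errors (PS)")
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        fig.savefig(out / "errors_by_speaker.png", dpi=120)
        plt.close(fig)
    if "predictions" in tables and len(tables["predictions"]):
        df = tables["predictions"]
        vote_df = df[df["method"] == "voting"]
        if len(vote_df) and "votes_case" in vote_df.columns:
            fig, ax = plt.subplots(figsize=(8, 3))
            colors = vote_df["actual"].map({"case": "tab:blue", "control": "tab:orange"})
            ax.bar(vote_df["speaker_id"], vote_df["votes_case"].astype(float), color=colors)
            ax.set_ylabel("classifications into cases")
            ax.tick_params(axis="x", rotation=90, labelsize=6)
            fig.tight_layout()
            fig.savefig(out / "votes_by_speaker.png", dpi=120)
            plt.close(fig)
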