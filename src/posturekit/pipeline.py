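"""Stage orchestration: simulate -> extract -> analyze, with run manifests.

Each stage is an ordinary library function usable without the CLI; the CLI
in :mod:`posturekit.cli` is a thin wrapper.  Every run is reproducible from
(config, seed) alone, and the manifest records the config hash, software
version, per-trial status and timestamps.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .features import FEATURE_NAMES, FeatureError, aggregate_subject, assemble_features
from .io import read_feature_table, read_trial, write_feature_table, write_json, write_trial
from .plans import TrialRecording
from .preprocess import PreprocessError, process_trial
from .segment import SegmentationError, segment
from .stats import StatsReport, run_analysis
from .synth import iter_cohort

__all__ = [
    "extract_trial_features",
    "extract_cohort_features",
    "simulate",
    "extract",
    "analyze",
    "run_all",
]

log = logging.getLogger("posturekit")


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


def _trial_id(rec: TrialRecording) -> str:
    m = rec.meta
    if {"subject", "condition", "trial"} <= m.keys():
        return f"S{int(m['subject']):03d}_{m['condition']}_T{int(m['trial'])}"
    return m.get("id", "trial")


def extract_trial_features(rec: TrialRecording, config: PipelineConfig) -> dict[str, float]:
    """Preprocess, segment and assemble the 29 features of one recording."""
    processed = process_trial(
        rec,
        kinematic_cutoff=config.kinematic_cutoff_hz,
        emg_band=config.emg_band_hz,
        emg_envelope_cutoff=config.emg_envelope_cutoff_hz,
        eeg_band=config.eeg_band_hz,
        order=config.filter_order,
    )
    seg = segment(
        processed,
        v_thresh=config.v_thresh,
        cop_onset_fraction=config.cop_onset_fraction,
        apa_search_window=config.apa_search_window_s,
        min_duration=config.min_phase_duration_s,
    )
    return assemble_features(
        processed, seg, n_cycles=config.n_cycles, freq_step=config.freq_step_hz
    )


def extract_cohort_features(
    trials: Iterable[TrialRecording], config: PipelineConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """Feature table (one row per subject-condition) plus per-trial failures.

    A subject-condition survives as long as at least one of its trials
    extracts cleanly; failed trials are logged and reported, not fatal.
    """
    per_group: dict[tuple[int, str], list[dict[str, float]]] = {}
    failures: list[dict] = []
    n_ok = 0
    for rec in trials:
        tid = _trial_id(rec)
        try:
            feats = extract_trial_features(rec, config)
        except (PreprocessError, SegmentationError, FeatureError) as err:
            log.warning("trial %s failed: %s", tid, err)
            failures.append({"trial": tid, "error": str(err), "type": type(err).__name__})
            continue
        key = (int(rec.meta.get("subject", 0)), str(rec.meta.get("condition", "unknown")))
        per_group.setdefault(key, []).append(feats)
        n_ok += 1
    if not per_group:
        raise FeatureError("no trial produced features")
    how = config.cohort.aggregate
    rows = []
    for (subject, condition), vectors in sorted(per_group.items()):
        row = {"subject": subject, "condition": condition}
        row.update(aggregate_subject(vectors, how=how))
        rows.append(row)
    table = pd.DataFrame(rows, columns=["subject", "condition", *FEATURE_NAMES])
    log.info("extracted %d trials into %d subject-condition rows (%d failures)",
             n_ok, len(table), len(failures))
    return table, failures


# ---------------------------------------------------------------------------
# on-disk stages


def simulate(config: PipelineConfig, outdir: Path | str, overwrite: bool = False) -> Path:
    """Write the synthetic cohort to ``outdir`` (trial CSVs + manifest)."""
    outdir = Path(outdir)
    trials_dir = outdir / "trials"
    if trials_dir.exists() and any(trials_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{trials_dir} is not empty; pass overwrite to replace it")
    trials_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    started = _now()
    for rec in iter_cohort(config.cohort):
        tid = _trial_id(rec)
        path = trials_dir / f"{tid}.csv"
        write_trial(rec, path)
        manifest_rows.append(
            {"trial": tid, "subject": rec.meta["subject"], "condition": rec.meta["condition"],
             "trial_index": rec.meta["trial"], "path": str(path.relative_to(outdir)),
             "status": "ok"}
        )
    manifest = pd.DataFrame(manifest_rows)
    from .io import atomic_write_text

    atomic_write_text(outdir / "cohort_manifest.csv", manifest.to_csv(index=False))
    write_json(outdir / "run_manifest.json", {
        "stage": "simulate",
        "config_hash": config.content_hash(),
        "version": __version__,
        "seed": config.cohort.seed,
        "n_trials": len(manifest_rows),
        "started": started,
        "finished": _now(),
    })
    config.to_yaml(outdir / "config.yaml")
    return outdir


def extract(indir: Path | str, config: PipelineConfig, out_csv: Path | str) -> pd.DataFrame:
    """Read every trial CSV under ``indir`` and write the feature table."""
    indir = Path(indir)
    trials_dir = indir / "trials" if (indir / "trials").is_dir() else indir
    paths = sorted(trials_dir.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trial CSVs found under {trials_dir}")
    table, failures = extract_cohort_features((read_trial(p) for p in paths), config)
    write_feature_table(table, out_csv)
    write_json(Path(out_csv).with_suffix(".manifest.json"), {
        "stage": "extract",
        "config_hash": config.content_hash(),
        "version": __version__,
        "n_input_trials": len(paths),
        "n_failed_trials": len(failures),
        "failures": failures,
        "finished": _now(),
    })
    return table


def analyze(
    table: pd.DataFrame | Path | str, config: PipelineConfig, out_prefix: Path | str
) -> StatsReport:
    """Run the statistics stage and write JSON + markdown reports."""
    if not isinstance(table, pd.DataFrame):
        table = read_feature_table(table)
    report = run_analysis(
        table,
        k=config.k,
        alpha=config.alpha,
        seed=config.analysis_seed,
        n_trees=config.n_trees,
    )
    out_prefix = Path(out_prefix)
    report.to_json(out_prefix.with_suffix(".json"))
    from .io import atomic_write_text

    atomic_write_text(out_prefix.with_suffix(".md"), report.to_markdown() + "\n")
    return report


def run_all(config: PipelineConfig, outdir: Path | str, overwrite: bool = False) -> StatsReport:
    """simulate -> extract -> analyze, chained under one output directory."""
    outdir = Path(outdir)
    simulate(config, outdir, overwrite=overwrite)
    table = extract(outdir, config, outdir / "features.csv")
    report = analyze(table, config, outdir / "report")
    return report
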