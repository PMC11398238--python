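"""File formats: long-format trial CSV + JSON sidecar, feature tables, manifests.

All writes are atomic (write to a temporary file in the destination
directory, then rename), so interrupted runs never leave truncated files.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .plans import EEG_CHANNELS, MUSCLES, TrialRecording

__all__ = [
    "TRIAL_COLUMNS",
    "atomic_write_text",
    "write_trial",
    "read_trial",
    "write_feature_table",
    "read_feature_table",
    "write_json",
]

TRIAL_COLUMNS = (
    "time_s",
    "angle_deg",
    "cop_ap_mm",
    "emg_ra",
    "emg_es",
    "eeg_fp1",
    "eeg_fp2",
    "eeg_cz",
    "eeg_poz",
)


def atomic_write_text(path: Path | str, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path: Path | str, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_trial(rec: TrialRecording, path: Path | str) -> Path:
    """Write one trial as long-format CSV plus a JSON metadata sidecar."""
    path = Path(path)
    n = rec.n_samples
    frame = pd.DataFrame(
        {
            "time_s": np.arange(n) / rec.fs,
            "angle_deg": rec.angle,
            "cop_ap_mm": rec.cop_ap,
            "emg_ra": rec.emg["ra"],
            "emg_es": rec.emg["es"],
            "eeg_fp1": rec.eeg["fp1"],
            "eeg_fp2": rec.eeg["fp2"],
            "eeg_cz": rec.eeg["cz"],
            "eeg_poz": rec.eeg["poz"],
        }
    )
    atomic_write_text(path, frame.to_csv(index=False, float_format="%.17g"))
    sidecar = {
        "sampling_rate_hz": rec.fs,
        "baseline_window": list(rec.baseline_window),
        "meta": rec.meta,
        "ground_truth": rec.ground_truth,
    }
    write_json(path.with_suffix(".json"), sidecar)
    return path


def read_trial(path: Path | str) -> TrialRecording:
    """Read a trial CSV (+ sidecar if present) back into a TrialRecording."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: trial CSV missing columns {missing}")
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        fs = float(sidecar["sampling_rate_hz"])
        baseline = tuple(sidecar["baseline_window"])
        meta = sidecar.get("meta", {})
        ground_truth = sidecar.get("ground_truth")
    else:
        dt = float(frame["time_s"].iloc[1] - frame["time_s"].iloc[0])
        fs = 1.0 / dt
        baseline = (0, int(round(10.0 * fs)))
        meta, ground_truth = {}, None
    return TrialRecording(
        fs=fs,
        angle=frame["angle_deg"].to_numpy(),
        cop_ap=frame["cop_ap_mm"].to_numpy(),
        emg={m: frame[f"emg_{m}"].to_numpy() for m in MUSCLES},
        eeg={ch: frame[f"eeg_{ch}"].to_numpy() for ch in EEG_CHANNELS},
        baseline_window=(int(baseline[0]), int(baseline[1])),
        meta=meta,
        ground_truth=ground_truth,
    )


def write_feature_table(table: pd.DataFrame, path: Path | str) -> Path:
    """Tidy CSV: one row per subject-condition, 29 feature columns."""
    path = Path(path)
    cols = ["subject", "condition", *FEATURE_NAMES]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    # 17 significant digits so every float64 survives the text round trip
    atomic_write_text(path, table[cols].to_csv(index=False, float_format="%.17g"))
    schema = {
        "columns": cols,
        "n_features": len(FEATURE_NAMES),
        "feature_names": list(FEATURE_NAMES),
    }
    write_json(path.with_suffix(".schema.json"), schema)
    return path


def read_feature_table(path: Path | str) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("subject", "condition", *FEATURE_NAMES) if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing columns {missing}")
    return table
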