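"""Per-modality filtering, rectification and baseline normalization.

All filters are Butterworth designs applied zero-phase (forward-backward,
``sosfiltfilt``): offline analysis permits it, and phase alignment across
modalities is required because features are indexed by phase boundaries
detected on the kinematic channel.  Zero-phase application doubles the
effective order; the provenance record stores the design order.

Chain per modality:

* angle / COP: 4th-order low-pass, 6 Hz cutoff;
* EMG: 4th-order band-pass 10-400 Hz, full-wave rectification, optional
  envelope smoothing, then division by the mean rectified activity of the
  quiet-standing baseline window (x100, percent of baseline);
* EEG: 4th-order band-pass 1-30 Hz, then an optional artifact-removal hook
  (any callable mapping the channel dict to a channel dict; identity by
  default -- component-based artifact rejection is intentionally pluggable
  rather than built in).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import signal

from .plans import TrialRecording

__all__ = [
    "filter_kinematic",
    "process_emg",
    "filter_eeg",
    "ProcessedTrial",
    "process_trial",
]


class PreprocessError(ValueError):
    """Invalid input to a preprocessing stage."""


def _sos_lowpass(cutoff: float, fs: float, order: int) -> np.ndarray:
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


def _sos_bandpass(band: tuple[float, float], fs: float, order: int) -> np.ndarray:
    # second-order sections for numerical stability with a 1 Hz edge at 1 kHz
    return signal.butter(order, band, btype="band", fs=fs, output="sos")


def _check_length(x: np.ndarray, order: int) -> None:
    if len(x) <= 3 * (2 * order + 1):
        raise PreprocessError(f"series of length {len(x)} too short for order-{order} filtfilt")


def filter_kinematic(x: np.ndarray, fs: float, cutoff: float = 6.0, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass for angle and COP channels (DC gain 1)."""
    if fs <= 2 * cutoff:
        raise PreprocessError(f"fs={fs} must exceed twice the {cutoff} Hz cutoff")
    x = np.asarray(x, dtype=float)
    _check_length(x, order)
    return signal.sosfiltfilt(_sos_lowpass(cutoff, fs, order), x)


def process_emg(
    x: np.ndarray,
    fs: float,
    baseline_window: tuple[int, int],
    band: tuple[float, float] = (10.0, 400.0),
    order: int = 4,
    envelope_cutoff: float | None = 6.0,
) -> np.ndarray:
    """Band-pass, rectify, smooth and normalize one EMG channel.

    Returns the envelope in percent of the mean rectified quiet-standing
    baseline; the baseline-window mean of the output is therefore ~100.
    ``envelope_cutoff=None`` skips smoothing and normalizes the raw
    rectified signal.
    """
    if fs <= 2 * band[1]:
        raise PreprocessError(f"fs={fs} must exceed twice the EMG band edge {band[1]} Hz")
    b0, b1 = baseline_window
    if (b1 - b0) / fs < 10.0 - 1e-9:
        raise PreprocessError("EMG baseline window must span at least 10 s")
    x = np.asarray(x, dtype=float)
    _check_length(x, order)
    filtered = signal.sosfiltfilt(_sos_bandpass(band, fs, order), x)
    rectified = np.abs(filtered)
    if envelope_cutoff is not None:
        env = signal.sosfiltfilt(_sos_lowpass(envelope_cutoff, fs, order), rectified)
        env = np.clip(env, 0.0, None)  # low-pass ringing may dip below zero
    else:
        env = rectified
    baseline_mean = float(np.mean(rectified[b0:b1]))
    if baseline_mean <= 0:
        raise PreprocessError("zero baseline activity: EMG normalization undefined")
    return 100.0 * env / baseline_mean


def filter_eeg(
    x: np.ndarray, fs: float, band: tuple[float, float] = (1.0, 30.0), order: int = 4
) -> np.ndarray:
    """Zero-phase 1-30 Hz band-pass for one EEG channel."""
    if fs <= 2 * band[1]:
        raise PreprocessError(f"fs={fs} must exceed twice the EEG band edge {band[1]} Hz")
    x = np.asarray(x, dtype=float)
    _check_length(x, order)
    return signal.sosfiltfilt(_sos_bandpass(band, fs, order), x)


ArtifactHook = Callable[[Mapping[str, np.ndarray]], Mapping[str, np.ndarray]]


@dataclass
class ProcessedTrial:
    """Filtered channels of one trial plus the filter provenance."""

    fs: float
    angle_f: np.ndarray
    cop_f: np.ndarray
    emg_env: dict[str, np.ndarray]  # percent of baseline, >= 0
    eeg_f: dict[str, np.ndarray]
    baseline_window: tuple[int, int]
    meta: dict = field(default_factory=dict)
    ground_truth: dict | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.angle_f)


def process_trial(
    rec: TrialRecording,
    kinematic_cutoff: float = 6.0,
    emg_band: tuple[float, float] = (10.0, 400.0),
    emg_envelope_cutoff: float | None = 6.0,
    eeg_band: tuple[float, float] = (1.0, 30.0),
    order: int = 4,
    artifact_hook: ArtifactHook | None = None,
) -> ProcessedTrial:
    """Apply the full per-modality chain to one recording."""
    eeg_f = {ch: filter_eeg(x, rec.fs, eeg_band, order) for ch, x in rec.eeg.items()}
    if artifact_hook is not None:
        eeg_f = dict(artifact_hook(eeg_f))
    return ProcessedTrial(
        fs=rec.fs,
        angle_f=filter_kinematic(rec.angle, rec.fs, kinematic_cutoff, order),
        cop_f=filter_kinematic(rec.cop_ap, rec.fs, kinematic_cutoff, order),
        emg_env={
            m: process_emg(x, rec.fs, rec.baseline_window, emg_band, order, emg_envelope_cutoff)
            for m, x in rec.emg.items()
        },
        eeg_f=eeg_f,
        baseline_window=rec.baseline_window,
        meta=dict(rec.meta),
        ground_truth=rec.ground_truth,
        provenance={
            "kinematic_filter": {"type": "butterworth", "order": order, "cutoff_hz": kinematic_cutoff, "zero_phase": True},
            "emg_filter": {"type": "butterworth", "order": order, "band_hz": list(emg_band), "zero_phase": True,
                           "rectified": True, "envelope_cutoff_hz": emg_envelope_cutoff,
                           "normalization": "percent of mean rectified baseline"},
            "eeg_filter": {"type": "butterworth", "order": order, "band_hz": list(eeg_band), "zero_phase": True,
                           "artifact_hook": getattr(artifact_hook, "__name__", None) if artifact_hook else None},
        },
    )
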