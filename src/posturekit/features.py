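"""The 29 per-trial features: kinematics, COP, EMG, co-contraction, EEG.

Feature inventory (canonical order):

* 3 kinematic: maximum trunk flexion angle, maximum flexion and extension
  angular velocities;
* 2 COP: maximum anterior-posterior displacement during the APA phase and
  during flexion;
* 8 EMG: mean rectus abdominis (RA) and erector spinae (ES) normalized
  activity per phase;
* 4 co-contraction: mean CCI = 2*EMGlow/(EMGlow+EMGhigh) per phase;
* 12 EEG: alpha/beta ratio-of-log-band-powers for the Fp (mean of Fp1 and
  Fp2, averaged after all other computations), Cz and POz regions per phase.

The alpha/beta ratio divides *log-transformed* band powers, which is
scale-sensitive: powers are expressed in µV² with planted task powers well
above 1 and floored at 1e-12, and ratios whose log-beta denominator is
within 1e-3 of zero are rejected rather than returned.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pywt

from .bands import (
    BANDS,
    DEFAULT_FREQ_STEP,
    DEFAULT_N_CYCLES,
    band_frequency_grid,
    morlet_wavelet_name,
)
from .plans import PHASES
from .preprocess import ProcessedTrial
from .segment import PhaseSegmentation, angular_velocity

__all__ = [
    "FEATURE_NAMES",
    "FeatureError",
    "UndefinedRatioError",
    "kinematic_features",
    "cop_features",
    "emg_phase_means",
    "cci",
    "phase_mean_cci",
    "morlet_band_power",
    "alpha_beta_ratio",
    "assemble_features",
    "aggregate_subject",
]

EEG_REGIONS = ("fp", "cz", "poz")

FEATURE_NAMES: tuple[str, ...] = (
    "max_flexion_angle",
    "max_flexion_velocity",
    "max_extension_velocity",
    "max_cop_apa",
    "max_cop_flexion",
    *[f"ra_mean_{p}" for p in PHASES],
    *[f"es_mean_{p}" for p in PHASES],
    *[f"cci_mean_{p}" for p in PHASES],
    *[f"ab_ratio_{r}_{p}" for r in EEG_REGIONS for p in PHASES],
)
assert len(FEATURE_NAMES) == 29

#: numerical floor for band power before the log transform, µV²
POWER_FLOOR = 1e-12

#: |ln(P_beta)| below this is rejected as an undefined ratio denominator
LOG_GUARD = 1e-3


class FeatureError(ValueError):
    """A feature could not be computed for this trial."""


class UndefinedRatioError(FeatureError):
    """log beta power too close to zero for a meaningful ratio of logs."""


def _window(seg: PhaseSegmentation, phase: str) -> tuple[int, int]:
    i0, i1 = seg.window(phase)
    if i1 <= i0:
        raise FeatureError(f"empty {phase} phase window [{i0}, {i1})")
    return i0, i1


def kinematic_features(
    angle_f: np.ndarray, velocity: np.ndarray, seg: PhaseSegmentation
) -> dict[str, float]:
    """Peak angle and per-direction peak angular velocities.

    The maximum angle is searched over flexion plus switch because the
    angular peak can fall inside the switch window under threshold-based
    phase bounds (the velocity drops below threshold just before the peak).
    """
    f0, _ = _window(seg, "flexion")
    _, s1 = _window(seg, "switch")
    x0, x1 = _window(seg, "extension")
    return {
        "max_flexion_angle": float(np.max(angle_f[f0:s1])),
        "max_flexion_velocity": float(np.max(velocity[slice(*seg.window("flexion"))])),
        "max_extension_velocity": float(np.max(np.abs(velocity[x0:x1]))),
    }


def cop_features(
    cop_f: np.ndarray,
    seg: PhaseSegmentation,
    reference_window: float = 0.5,
) -> dict[str, float]:
    """Maximum COP-AP displacements during the APA phase and during flexion.

    Displacements are referenced to the mean COP over ``reference_window``
    seconds immediately preceding the APA onset.
    """
    a0, a1 = _window(seg, "apa")
    f0, f1 = _window(seg, "flexion")
    r0 = max(0, a0 - int(round(reference_window * seg.fs)))
    if a0 - r0 < 1:
        raise FeatureError("no pre-APA reference window available")
    ref = float(np.mean(cop_f[r0:a0]))
    return {
        "max_cop_apa": float(np.max(np.abs(cop_f[a0:a1] - ref))),
        "max_cop_flexion": float(np.max(cop_f[f0:f1] - ref)),
    }


def emg_phase_means(
    emg_env: Mapping[str, np.ndarray], seg: PhaseSegmentation
) -> dict[str, float]:
    """Mean normalized muscle activity (percent of baseline) per phase."""
    out: dict[str, float] = {}
    for muscle, env in emg_env.items():
        for phase in PHASES:
            i0, i1 = _window(seg, phase)
            out[f"{muscle}_mean_{phase}"] = float(np.mean(env[i0:i1]))
    return out


def cci(
    env_ra: np.ndarray, env_es: np.ndarray, zero_policy: str = "zero"
) -> np.ndarray:
    """Per-sample co-contraction index ``2*EMGlow/(EMGlow+EMGhigh)``.

    ``EMGlow``/``EMGhigh`` are the lesser/greater of the two envelopes at
    each sample.  Samples where both envelopes are zero are 0 under the
    default policy ("co-contraction of silent muscles is absent") or NaN
    under ``zero_policy="exclude"`` (dropped from phase means).
    """
    ra = np.asarray(env_ra, dtype=float)
    es = np.asarray(env_es, dtype=float)
    if ra.shape != es.shape:
        raise FeatureError("CCI envelopes must have identical shape")
    if np.any(ra < 0) or np.any(es < 0):
        raise FeatureError("CCI envelopes must be non-negative")
    if zero_policy not in ("zero", "exclude"):
        raise ValueError("zero_policy must be 'zero' or 'exclude'")
    low = np.minimum(ra, es)
    total = ra + es
    out = np.zeros_like(low)
    nz = total > 0
    out[nz] = 2.0 * low[nz] / total[nz]
    if zero_policy == "exclude":
        out[~nz] = np.nan
    return out


def phase_mean_cci(cci_series: np.ndarray, seg: PhaseSegmentation) -> dict[str, float]:
    """Mean CCI within each phase window (NaN samples excluded)."""
    out = {}
    for phase in PHASES:
        i0, i1 = _window(seg, phase)
        window = cci_series[i0:i1]
        if np.all(np.isnan(window)):
            raise FeatureError(f"all CCI samples undefined in {phase} phase")
        out[f"cci_mean_{phase}"] = float(np.nanmean(window))
    return out


def morlet_band_power(
    x: np.ndarray,
    fs: float,
    window: tuple[int, int],
    band: tuple[float, float],
    n_cycles: float = DEFAULT_N_CYCLES,
    freq_step: float = DEFAULT_FREQ_STEP,
    pad: float = 1.0,
    floor: float = POWER_FLOOR,
) -> float:
    """Natural-log Morlet band power of ``x`` over a phase window.

    A continuous complex-Morlet transform is evaluated on a 1 Hz analysis
    grid across the band; power is averaged over grid frequencies and window
    time, floored at ``floor``, and log-transformed.  The transform is run on
    a window padded by ``pad`` seconds of surrounding signal (clipped at the
    series edges) so wavelet edge effects fall outside the scored window.
    """
    x = np.asarray(x, dtype=float)
    i0, i1 = window
    f_lo, f_hi = band
    if i1 <= i0:
        raise FeatureError(f"empty analysis window [{i0}, {i1})")
    min_len = 2.0 * fs / f_lo  # two cycles of the band's lower edge
    if i1 - i0 < min_len:
        raise FeatureError(
            f"window of {(i1 - i0) / fs:.3f} s too short for the {f_lo}-{f_hi} Hz band: "
            f"needs >= 2 cycles of {f_lo} Hz ({min_len / fs:.3f} s)"
        )
    p = int(round(pad * fs))
    a, b = max(0, i0 - p), min(len(x), i1 + p)
    freqs = band_frequency_grid((f_lo, f_hi), freq_step)
    scales = fs / freqs  # cmor centre frequency is 1.0
    coef, _ = pywt.cwt(x[a:b], scales, morlet_wavelet_name(n_cycles), method="fft")
    w = coef[:, i0 - a : i1 - a]
    # a unit-amplitude tone at the analysis frequency yields |coef| = 0.5*sqrt(scale),
    # so this normalization makes a tone of amplitude A contribute power A**2/2
    per_freq = np.mean(np.abs(w) ** 2, axis=1) / (0.5 * scales)
    return float(np.log(max(float(np.mean(per_freq)), floor)))


def alpha_beta_ratio(
    eeg_f: Mapping[str, np.ndarray],
    seg: PhaseSegmentation,
    n_cycles: float = DEFAULT_N_CYCLES,
    freq_step: float = DEFAULT_FREQ_STEP,
) -> dict[str, float]:
    """Alpha/beta ratio of log band powers per region and phase.

    Per channel and phase the ratio is ``ln(P_alpha) / ln(P_beta)``; the Fp
    region entry is the arithmetic mean of the Fp1 and Fp2 ratios, averaged
    only after the per-channel ratios are formed.
    """
    per_channel: dict[str, dict[str, float]] = {}
    for ch, x in eeg_f.items():
        per_channel[ch] = {}
        for phase in PHASES:
            win = _window(seg, phase)
            log_a = morlet_band_power(x, seg.fs, win, BANDS["alpha"], n_cycles, freq_step)
            log_b = morlet_band_power(x, seg.fs, win, BANDS["beta"], n_cycles, freq_step)
            if abs(log_b) < LOG_GUARD:
                raise UndefinedRatioError(
                    f"undefined alpha/beta ratio for channel {ch!r}, phase {phase!r}: "
                    f"|ln(P_beta)| = {abs(log_b):.2e} < {LOG_GUARD}"
                )
            per_channel[ch][phase] = log_a / log_b
    out: dict[str, float] = {}
    for phase in PHASES:
        out[f"ab_ratio_fp_{phase}"] = 0.5 * (
            per_channel["fp1"][phase] + per_channel["fp2"][phase]
        )
        out[f"ab_ratio_cz_{phase}"] = per_channel["cz"][phase]
        out[f"ab_ratio_poz_{phase}"] = per_channel["poz"][phase]
    return out


def assemble_features(
    processed: ProcessedTrial,
    seg: PhaseSegmentation,
    cci_zero_policy: str = "zero",
    n_cycles: float = DEFAULT_N_CYCLES,
    freq_step: float = DEFAULT_FREQ_STEP,
) -> dict[str, float]:
    """All 29 features of one trial, canonically named and ordered."""
    velocity = angular_velocity(processed.angle_f, processed.fs)
    values: dict[str, float] = {}
    values.update(kinematic_features(processed.angle_f, velocity, seg))
    values.update(cop_features(processed.cop_f, seg))
    values.update(emg_phase_means(processed.emg_env, seg))
    cci_series = cci(processed.emg_env["ra"], processed.emg_env["es"], cci_zero_policy)
    values.update(phase_mean_cci(cci_series, seg))
    values.update(alpha_beta_ratio(processed.eeg_f, seg, n_cycles, freq_step))
    ordered = {name: values[name] for name in FEATURE_NAMES}
    return ordered


def aggregate_subject(
    trial_vectors: Sequence[Mapping[str, float]], how: str = "mean"
) -> dict[str, float]:
    """Feature-wise reduction of one subject-condition's trial vectors."""
    if len(trial_vectors) == 0:
        raise FeatureError("cannot aggregate an empty set of trial vectors")
    if how not in ("mean", "median"):
        raise ValueError("how must be 'mean' or 'median'")
    frame = pd.DataFrame(list(trial_vectors))
    reduced = frame.mean() if how == "mean" else frame.median()
    return {name: float(reduced[name]) for name in FEATURE_NAMES}
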