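"""Synthetic trial and paired-cohort generator with plantable ground truth.

Every downstream stage of the pipeline (filtering, phase segmentation,
feature extraction, statistics) can be validated against this module because
each generated signal carries closed-form planted parameters:

* the kinematic trajectory is raised-cosine per segment, so the planted peak
  angle and peak angular velocities are exact analytic properties;
* the COP trace is raised-cosine per segment, so the 5%-of-peak-speed APA
  onset has a closed-form crossing time;
* the EMG carrier is amplitude-modulated Gaussian noise whose rectified
  envelope expectation per phase is ``gain * baseline_mean``;
* the EEG channels are phase-enveloped band oscillators plus pink noise whose
  planted band powers follow the package's Morlet band-power convention.

A cohort emulates a paired two-condition study (vision / no-vision): each
subject's parameters are drawn once and shifted by the configured condition
effects, whose defaults are the vision-to-no-vision median differences
reported for this task (lower peak flexion angle, faster peak flexion
velocity, smaller anterior COP excursion, higher switch-phase POz alpha/beta
ratio without vision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .plans import (
    EEG_CHANNELS,
    ENVELOPE_SEGMENTS,
    MUSCLES,
    PHASES,
    CopPlan,
    EegPlan,
    EmgPlan,
    KinematicPlan,
    Timeline,
    TrialRecording,
)

__all__ = [
    "kinematic_profile",
    "cop_profile",
    "emg_profile",
    "eeg_profile",
    "generate_trial",
    "ParamSpec",
    "CohortConfig",
    "default_cohort_params",
    "draw_cohort_parameters",
    "trial_from_parameters",
    "generate_cohort",
    "iter_cohort",
    "planted_feature_table",
]

#: IQR-to-standard-deviation conversion for a normal distribution
_IQR_TO_SD = 1.3489795


def _n_samples(duration: float, fs: float) -> int:
    return int(round(duration * fs))


def _raised_cosine(t: np.ndarray, duration: float) -> np.ndarray:
    """Smooth 0 -> 1 transition over [0, duration]."""
    return 0.5 * (1.0 - np.cos(np.pi * t / duration))


def kinematic_profile(plan: KinematicPlan, fs: float) -> np.ndarray:
    """Trunk angle series (degrees) realizing the raised-cosine plan.

    The output's maximum equals ``plan.peak_angle`` exactly (the angle is held
    at the peak for the whole switch segment) and the analytic peak of
    ``d(theta)/dt`` during flexion equals ``plan.peak_flex_velocity``.
    """
    timeline = Timeline.from_plans(plan, CopPlan(apa_lead_time=min(0.3, plan.pre_movement_hold / 2)))
    n = _n_samples(timeline.total_duration, fs)
    t = np.arange(n) / fs
    angle = np.zeros(n)
    a = plan.peak_angle
    if a == 0:
        return angle
    t0, t_fe = timeline.movement_start, timeline.flexion_end
    t_es, t_me = timeline.extension_start, timeline.movement_end
    m = (t >= t0) & (t < t_fe)
    angle[m] = a * _raised_cosine(t[m] - t0, plan.flexion_duration)
    m = (t >= t_fe) & (t < t_es)
    angle[m] = a
    m = (t >= t_es) & (t < t_me)
    angle[m] = a * (1.0 - _raised_cosine(t[m] - t_es, plan.extension_duration))
    return angle


def cop_profile(plan: CopPlan, timeline: Timeline, fs: float) -> np.ndarray:
    """COP-AP series (mm, anterior positive) for a planted trial.

    A raised-cosine posterior excursion of amplitude ``apa_amplitude`` starts
    ``apa_lead_time`` before movement start and peaks (most posterior) exactly
    at flexion onset; the anterior excursion then rises to exactly
    ``flexion_displacement`` at peak flexion and is held through the switch
    segment before returning to baseline during extension.
    """
    n = _n_samples(timeline.total_duration, fs)
    t = np.arange(n) / fs
    cop = np.zeros(n)
    d, f = plan.apa_amplitude, plan.flexion_displacement
    ta, t0 = timeline.apa_start, timeline.movement_start
    t_fe, t_es, t_me = timeline.flexion_end, timeline.extension_start, timeline.movement_end
    m = (t >= ta) & (t < t0)
    cop[m] = -d * _raised_cosine(t[m] - ta, t0 - ta)
    if t_fe > t0:
        m = (t >= t0) & (t < t_fe)
        cop[m] = -d + (f + d) * _raised_cosine(t[m] - t0, t_fe - t0)
    m = (t >= t_fe) & (t < t_es)
    cop[m] = f
    if t_me > t_es:
        m = (t >= t_es) & (t < t_me)
        cop[m] = f * (1.0 - _raised_cosine(t[m] - t_es, t_me - t_es))
    return cop


def _segment_envelope(
    timeline: Timeline, n: int, fs: float, level: Mapping[str, float]
) -> np.ndarray:
    """Piecewise-constant envelope: quiet level outside the movement segments."""
    env = np.full(n, float(level.get("quiet", 0.0)))
    for seg, (lo, hi) in timeline.segment_bounds().items():
        i0, i1 = int(round(lo * fs)), int(round(hi * fs))
        env[i0:i1] = float(level.get(seg, level.get("quiet", 0.0)))
    return env


def emg_profile(
    plan: EmgPlan, timeline: Timeline, fs: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Zero-mean broadband EMG carriers with planted rectified envelopes.

    The carrier is Gaussian, so a target rectified mean ``m`` requires a
    carrier standard deviation ``m * sqrt(pi/2)``.
    """
    n = _n_samples(timeline.total_duration, fs)
    out: dict[str, np.ndarray] = {}
    for muscle in MUSCLES:
        sigma0 = plan.baseline_mean * math.sqrt(math.pi / 2.0)
        levels = {seg: sigma0 * plan.gain(muscle, seg) for seg in ENVELOPE_SEGMENTS}
        sigma = _segment_envelope(timeline, n, fs, levels)
        x = sigma * rng.standard_normal(n)
        if plan.noise_sd > 0:
            x = x + plan.noise_sd * rng.standard_normal(n)
        out[muscle] = x
    return out


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via FFT spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # remove DC
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def eeg_profile(
    plan: EegPlan, timeline: Timeline, fs: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Four-channel EEG: phase-enveloped band oscillators plus pink noise."""
    n = _n_samples(timeline.total_duration, fs)
    t = np.arange(n) / fs
    out: dict[str, np.ndarray] = {}
    for ch in EEG_CHANNELS:
        x = np.zeros(n)
        for band, f0 in plan.oscillator_freqs.items():
            levels = {seg: plan.amplitude(ch, band, seg) for seg in ENVELOPE_SEGMENTS}
            env = _segment_envelope(timeline, n, fs, levels)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x = x + env * np.cos(2.0 * np.pi * f0 * t + phase)
        if plan.pink_sd > 0:
            x = x + plan.pink_sd * pink_noise(n, rng)
        out[ch] = x
    return out


def generate_trial(
    kin: KinematicPlan,
    cop: CopPlan,
    emg: EmgPlan | None = None,
    eeg: EegPlan | None = None,
    fs: float = 1000.0,
    seed: int = 0,
    meta: Mapping | None = None,
) -> TrialRecording:
    """Generate one synchronized trial; deterministic for a fixed seed."""
    emg = emg if emg is not None else EmgPlan()
    eeg = eeg if eeg is not None else EegPlan.from_ratio_targets({})
    timeline = Timeline.from_plans(kin, cop)
    rng = np.random.default_rng(seed)
    angle = kinematic_profile(kin, fs)
    cop_ap = cop_profile(cop, timeline, fs)
    emg_series = emg_profile(emg, timeline, fs, rng)
    eeg_series = eeg_profile(eeg, timeline, fs, rng)
    ground_truth = {
        "peak_angle": kin.peak_angle,
        "peak_flex_velocity": kin.peak_flex_velocity,
        "peak_ext_velocity": kin.peak_ext_velocity,
        "apa_amplitude": cop.apa_amplitude,
        "flexion_displacement": cop.flexion_displacement,
        "apa_lead_time": cop.apa_lead_time,
        "switch_duration": kin.switch_duration,
        "emg_gains": {m: {s: emg.gain(m, s) for s in ENVELOPE_SEGMENTS} for m in MUSCLES},
        "timeline": {
            "apa_start": timeline.apa_start,
            "movement_start": timeline.movement_start,
            "flexion_end": timeline.flexion_end,
            "extension_start": timeline.extension_start,
            "movement_end": timeline.movement_end,
        },
        "seed": int(seed),
    }
    return TrialRecording(
        fs=fs,
        angle=angle,
        cop_ap=cop_ap,
        emg=emg_series,
        eeg=eeg_series,
        baseline_window=(0, _n_samples(kin.baseline_duration, fs)),
        meta=dict(meta or {}),
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# paired cohorts


@dataclass(frozen=True)
class ParamSpec:
    """Per-condition distribution of one planted parameter.

    Subject-level values are drawn ``Normal(median, IQR/1.349)`` in the vision
    condition; the no-vision value of the same subject is shifted by
    ``median_novision - median``.  Trial-to-trial scatter is
    ``Normal(0, within_frac * sd)``, drawn independently per trial.
    """

    median: float
    iqr: tuple[float, float]
    median_novision: float | None = None  # None -> no condition effect
    within_frac: float = 0.3
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        q1, q3 = self.iqr
        if not q3 > q1:
            raise ValueError(f"degenerate IQR {self.iqr}: upper quartile must exceed lower")
        if self.within_frac < 0:
            raise ValueError("within_frac must be >= 0")

    @property
    def sd(self) -> float:
        q1, q3 = self.iqr
        return (q3 - q1) / _IQR_TO_SD

    @property
    def effect_shift(self) -> float:
        return 0.0 if self.median_novision is None else self.median_novision - self.median

    def clip(self, value: float) -> float:
        return float(min(max(value, self.lo), self.hi))


def default_cohort_params() -> dict[str, ParamSpec]:
    """Planted-parameter distributions for the default paired cohort.

    Medians and IQRs of the condition-discriminating parameters follow the
    reported vision-condition group statistics; no-vision medians encode the
    reported effect directions.  Within-subject (trial) noise fractions are
    chosen so the strong kinematic effects, the marginal POz switch-phase
    ratio effect and the null EMG/CCI/APA-COP comparisons keep those
    characters at n=35.
    """
    p: dict[str, ParamSpec] = {
        "peak_angle": ParamSpec(48.8, (44.7, 57.5), 46.6, within_frac=0.15, lo=5.0),
        "peak_flex_velocity": ParamSpec(80.5, (66.6, 96.1), 89.7, within_frac=0.35, lo=20.0),
        "peak_ext_velocity": ParamSpec(70.0, (58.0, 82.0), within_frac=0.35, lo=20.0),
        "apa_amplitude": ParamSpec(7.0, (4.4, 10.6), 6.6, within_frac=1.0, lo=0.3),
        "flexion_displacement": ParamSpec(47.4, (33.8, 67.0), 35.0, within_frac=0.5, lo=1.0),
        "switch_duration": ParamSpec(0.5, (0.4, 0.6), within_frac=0.3, lo=0.05),
        "apa_lead_time": ParamSpec(0.3, (0.25, 0.35), within_frac=0.3, lo=0.1, hi=0.9),
        "ra_gain_apa": ParamSpec(1.52, (1.11, 2.44), 1.42, within_frac=1.0, lo=0.05),
        "ra_gain_flexion": ParamSpec(1.3, (1.0, 1.7), within_frac=1.0, lo=0.05),
        "ra_gain_switch": ParamSpec(1.1, (0.9, 1.4), within_frac=1.0, lo=0.05),
        "ra_gain_extension": ParamSpec(1.8, (1.3, 2.4), within_frac=1.0, lo=0.05),
        "es_gain_apa": ParamSpec(6.45, (5.18, 7.85), 6.33, within_frac=1.0, lo=0.05),
        "es_gain_flexion": ParamSpec(5.0, (3.8, 6.5), within_frac=1.0, lo=0.05),
        "es_gain_switch": ParamSpec(2.0, (1.5, 2.6), within_frac=1.0, lo=0.05),
        "es_gain_extension": ParamSpec(4.5, (3.4, 5.9), within_frac=1.0, lo=0.05),
    }
    ratio_defaults = {
        ("fp", "apa"): ParamSpec(1.0, (0.8, 1.2), within_frac=1.0, lo=0.3, hi=2.0),
        ("fp", "flexion"): ParamSpec(1.0, (0.8, 1.2), within_frac=1.0, lo=0.3, hi=2.0),
        ("fp", "switch"): ParamSpec(1.0, (0.8, 1.2), within_frac=1.0, lo=0.3, hi=2.0),
        ("fp", "extension"): ParamSpec(1.0, (0.7, 1.3), 1.1, within_frac=1.5, lo=0.3, hi=2.0),
        ("poz", "apa"): ParamSpec(1.0, (0.9, 1.2), 1.1, within_frac=2.0, lo=0.3, hi=2.0),
        ("poz", "switch"): ParamSpec(1.0, (0.8, 1.1), 1.1, within_frac=1.5, lo=0.3, hi=2.0),
    }
    for region in ("fp", "cz", "poz"):
        for phase in PHASES:
            spec = ratio_defaults.get(
                (region, phase), ParamSpec(1.0, (0.8, 1.2), within_frac=1.0, lo=0.3, hi=2.0)
            )
            p[f"ab_{region}_{phase}"] = spec
    return p


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a paired two-condition synthetic cohort."""

    n_subjects: int = 35
    n_trials: int = 3
    fs: float = 1000.0
    seed: int = 0
    params: Mapping[str, ParamSpec] = field(default_factory=default_cohort_params)
    baseline_duration: float = 10.0
    pre_movement_hold: float = 2.0
    tail_duration: float = 2.0
    emg_baseline_mean: float = 20.0
    emg_noise_sd: float = 1.0
    eeg_log_beta_power: float = 3.4
    eeg_theta_amplitude: float = 3.0
    eeg_pink_sd: float = 2.0
    aggregate: str = "mean"  # trial aggregation: "mean" or "median"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.aggregate not in ("mean", "median"):
            raise ValueError("aggregate must be 'mean' or 'median'")
        for name, spec in self.params.items():
            if not isinstance(spec, ParamSpec):
                raise TypeError(f"params[{name!r}] must be a ParamSpec")

    def without_effects(self) -> "CohortConfig":
        """Copy with all condition effects removed (null cohort)."""
        null_params = {
            name: replace(spec, median_novision=None) for name, spec in self.params.items()
        }
        return replace(self, params=null_params)


CONDITIONS = ("vision", "no_vision")


def draw_cohort_parameters(config: CohortConfig) -> pd.DataFrame:
    """Planted parameters for every (subject, condition, trial) row.

    Subject-level baselines are drawn once per subject, then shifted by the
    condition effect and jittered per trial, preserving the paired structure.
    One master seed spawns independent per-subject streams.
    """
    names = list(config.params)
    rows = []
    master = np.random.SeedSequence(config.seed)
    for subject, sub_ss in enumerate(master.spawn(config.n_subjects), start=1):
        rng = np.random.default_rng(sub_ss)
        base = {n: rng.normal(config.params[n].median, config.params[n].sd) for n in names}
        for condition in CONDITIONS:
            for trial in range(1, config.n_trials + 1):
                row: dict = {"subject": subject, "condition": condition, "trial": trial}
                for n in names:
                    spec = config.params[n]
                    value = base[n]
                    if condition == "no_vision":
                        value += spec.effect_shift
                    value += rng.normal(0.0, spec.within_frac * spec.sd)
                    row[n] = spec.clip(value)
                row["trial_seed"] = int(rng.integers(0, 2**31))
                rows.append(row)
    return pd.DataFrame(rows)


def trial_from_parameters(row: Mapping, config: CohortConfig) -> TrialRecording:
    """Realize one planted-parameter row as a full multichannel recording."""
    kin = KinematicPlan(
        peak_angle=row["peak_angle"],
        peak_flex_velocity=row["peak_flex_velocity"],
        peak_ext_velocity=row["peak_ext_velocity"],
        switch_duration=row["switch_duration"],
        pre_movement_hold=config.pre_movement_hold,
        baseline_duration=config.baseline_duration,
        tail_duration=config.tail_duration,
    )
    cop = CopPlan(
        apa_amplitude=row["apa_amplitude"],
        flexion_displacement=row["flexion_displacement"],
        apa_lead_time=row["apa_lead_time"],
    )
    gains = {
        muscle: {"quiet": 1.0, **{ph: float(row[f"{muscle}_gain_{ph}"]) for ph in PHASES}}
        for muscle in MUSCLES
    }
    emg = EmgPlan(
        baseline_mean=config.emg_baseline_mean, burst_gains=gains, noise_sd=config.emg_noise_sd
    )
    region_of = {"fp1": "fp", "fp2": "fp", "cz": "cz", "poz": "poz"}
    ratios = {
        ch: {"quiet": 1.0, **{ph: float(row[f"ab_{region_of[ch]}_{ph}"]) for ph in PHASES}}
        for ch in EEG_CHANNELS
    }
    eeg = EegPlan.from_ratio_targets(
        ratios,
        log_beta_power=config.eeg_log_beta_power,
        theta_amplitude=config.eeg_theta_amplitude,
        pink_sd=config.eeg_pink_sd,
    )
    meta = {
        "subject": int(row["subject"]),
        "condition": str(row["condition"]),
        "trial": int(row["trial"]),
    }
    rec = generate_trial(kin, cop, emg, eeg, fs=config.fs, seed=int(row["trial_seed"]), meta=meta)
    assert rec.ground_truth is not None
    rec.ground_truth["planted_features"] = planted_features(row)
    return rec


def iter_cohort(config: CohortConfig) -> Iterator[TrialRecording]:
    """Lazily generate every trial of the cohort (memory-friendly)."""
    table = draw_cohort_parameters(config)
    for _, row in table.iterrows():
        yield trial_from_parameters(row, config)


def generate_cohort(config: CohortConfig) -> list[TrialRecording]:
    """All ``n_subjects x 2 x n_trials`` recordings of the cohort."""
    return list(iter_cohort(config))


def planted_features(row: Mapping) -> dict[str, float]:
    """Map one planted-parameter row to its 29 ground-truth feature values."""
    feats: dict[str, float] = {
        "max_flexion_angle": float(row["peak_angle"]),
        "max_flexion_velocity": float(row["peak_flex_velocity"]),
        "max_extension_velocity": float(row["peak_ext_velocity"]),
        "max_cop_apa": float(row["apa_amplitude"]),
        "max_cop_flexion": float(row["flexion_displacement"]),
    }
    for muscle in MUSCLES:
        for ph in PHASES:
            feats[f"{muscle}_mean_{ph}"] = 100.0 * float(row[f"{muscle}_gain_{ph}"])
    for ph in PHASES:
        ra, es = float(row[f"ra_gain_{ph}"]), float(row[f"es_gain_{ph}"])
        lo, hi = min(ra, es), max(ra, es)
        feats[f"cci_mean_{ph}"] = 2.0 * lo / (lo + hi) if (lo + hi) > 0 else 0.0
    for region in ("fp", "cz", "poz"):
        for ph in PHASES:
            feats[f"ab_ratio_{region}_{ph}"] = float(row[f"ab_{region}_{ph}"])
    return feats


def planted_feature_table(config: CohortConfig) -> pd.DataFrame:
    """Ground-truth feature table, one row per subject-condition.

    This is the asymptote of the full signal -> preprocessing -> segmentation
    -> feature chain: the planted parameter of each trial mapped directly to
    its feature value and aggregated across trials, bypassing signal
    synthesis.  It serves as the oracle for the statistics stage.
    """
    params = draw_cohort_parameters(config)
    feats = pd.DataFrame([planted_features(r) for _, r in params.iterrows()])
    feats.insert(0, "subject", params["subject"].to_numpy())
    feats.insert(1, "condition", params["condition"].to_numpy())
    agg = "median" if config.aggregate == "median" else "mean"
    out = feats.groupby(["subject", "condition"], sort=True).agg(agg).reset_index()
    return out.drop(columns=[c for c in ("trial",) if c in out.columns])
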