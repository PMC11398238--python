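"""Plan types for synthetic trials and the trial container.

A *plan* holds the analytically plantable parameters of one modality of a
synthetic standing trunk flexion-extension trial: the raised-cosine kinematic
trajectory, the COP anticipatory (APA) and anterior excursions, the per-phase
EMG envelope gains, and the per-phase EEG band amplitudes.  Every planted
quantity is recoverable downstream, which is what makes the generator usable
as a ground-truth oracle for the analysis chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .bands import BandDefinition, amplitude_for_band_power

__all__ = [
    "PHASES",
    "EEG_CHANNELS",
    "MUSCLES",
    "KinematicPlan",
    "CopPlan",
    "EmgPlan",
    "EegPlan",
    "Timeline",
    "TrialRecording",
]

#: movement phases, in temporal order
PHASES = ("apa", "flexion", "switch", "extension")

EEG_CHANNELS = ("fp1", "fp2", "cz", "poz")
MUSCLES = ("ra", "es")

#: EMG/EEG envelope segments: the four movement phases plus quiet standing
ENVELOPE_SEGMENTS = ("quiet",) + PHASES


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class KinematicPlan:
    """Raised-cosine flexion-extension trajectory parameters.

    The flexion segment is ``theta(t) = A/2 * (1 - cos(pi*t/T_f))`` with
    ``T_f = pi*A / (2*v_flex)`` so that its analytic peak angular velocity is
    exactly ``peak_flex_velocity``; the extension segment is the mirrored
    profile with ``T_e = pi*A / (2*v_ext)``.  Between the two the angle is
    held at ``peak_angle`` for ``switch_duration`` seconds.
    """

    peak_angle: float = 48.8  # degrees
    peak_flex_velocity: float = 80.5  # degrees/s
    peak_ext_velocity: float = 70.0  # degrees/s
    switch_duration: float = 0.5  # s
    pre_movement_hold: float = 2.0  # s of quiet stance after the baseline
    baseline_duration: float = 10.0  # s, must be >= 10
    tail_duration: float = 2.0  # s of quiet stance after the movement

    def __post_init__(self) -> None:
        for name in (
            "peak_angle",
            "peak_flex_velocity",
            "peak_ext_velocity",
            "switch_duration",
            "pre_movement_hold",
            "baseline_duration",
            "tail_duration",
        ):
            _require_finite(name, getattr(self, name))
        if self.peak_angle < 0:
            raise ValueError("peak_angle must be >= 0")
        if self.peak_flex_velocity <= 0 or self.peak_ext_velocity <= 0:
            raise ValueError("peak velocities must be > 0")
        if min(self.switch_duration, self.pre_movement_hold, self.tail_duration) < 0:
            raise ValueError("durations must be >= 0")
        if self.baseline_duration < 10.0:
            raise ValueError("baseline_duration must be >= 10 s")

    @property
    def flexion_duration(self) -> float:
        return math.pi * self.peak_angle / (2.0 * self.peak_flex_velocity)

    @property
    def extension_duration(self) -> float:
        return math.pi * self.peak_angle / (2.0 * self.peak_ext_velocity)


@dataclass(frozen=True)
class CopPlan:
    """COP anterior-posterior excursion parameters (posterior negative)."""

    apa_amplitude: float = 7.0  # mm, posterior APA shift (magnitude)
    flexion_displacement: float = 47.4  # mm, peak anterior excursion
    apa_lead_time: float = 0.3  # s before flexion movement start

    def __post_init__(self) -> None:
        for name in ("apa_amplitude", "flexion_displacement", "apa_lead_time"):
            _require_finite(name, getattr(self, name))
        if self.apa_amplitude < 0 or self.flexion_displacement < 0:
            raise ValueError("COP excursion amplitudes must be >= 0")
        if self.apa_lead_time <= 0:
            raise ValueError("apa_lead_time must be > 0")


def _default_gains() -> dict[str, dict[str, float]]:
    return {
        "ra": {"quiet": 1.0, "apa": 1.52, "flexion": 1.3, "switch": 1.1, "extension": 1.8},
        "es": {"quiet": 1.0, "apa": 6.45, "flexion": 5.0, "switch": 2.0, "extension": 4.5},
    }


@dataclass(frozen=True)
class EmgPlan:
    """Amplitude-modulated broadband EMG carrier parameters.

    ``burst_gains[muscle][segment]`` multiplies the quiet-standing rectified
    envelope expectation ``baseline_mean`` in each segment, so the normalized
    phase-mean activity planted for a phase is ``100 * gain`` percent.
    """

    baseline_mean: float = 20.0  # arbitrary units (expected rectified level)
    burst_gains: Mapping[str, Mapping[str, float]] = field(default_factory=_default_gains)
    noise_sd: float = 1.0  # additive wideband measurement noise, same units

    def __post_init__(self) -> None:
        _require_finite("baseline_mean", self.baseline_mean)
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for muscle in MUSCLES:
            if muscle not in self.burst_gains:
                raise ValueError(f"burst_gains missing muscle {muscle!r}")
            for seg in ENVELOPE_SEGMENTS:
                g = self.burst_gains[muscle].get(seg, 1.0)
                _require_finite(f"gain[{muscle}][{seg}]", g)
                if g < 0:
                    raise ValueError("burst gains must be >= 0")

    def gain(self, muscle: str, segment: str) -> float:
        return float(self.burst_gains[muscle].get(segment, 1.0))


@dataclass(frozen=True)
class EegPlan:
    """Per-channel, per-segment oscillator amplitudes plus pink noise.

    ``amplitudes[channel][band][segment]`` is the sinusoid amplitude in µV for
    the band's oscillator (default centre frequencies 5.5 / 10 / 20 Hz for
    theta / alpha / beta).  Pink (1/f) noise of standard deviation ``pink_sd``
    is added so band extraction is non-trivial.
    """

    amplitudes: Mapping[str, Mapping[str, Mapping[str, float]]]
    oscillator_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"theta": 5.5, "alpha": 10.0, "beta": 20.0}
    )
    pink_sd: float = 2.0  # µV
    bands: BandDefinition = field(default_factory=BandDefinition)

    def __post_init__(self) -> None:
        if self.pink_sd < 0:
            raise ValueError("pink_sd must be >= 0")
        for band, f in self.oscillator_freqs.items():
            lo, hi = self.bands[band]
            if not lo <= f <= hi:
                raise ValueError(
                    f"oscillator frequency {f} Hz for band {band!r} outside [{lo}, {hi}] Hz"
                )
        for ch in EEG_CHANNELS:
            if ch not in self.amplitudes:
                raise ValueError(f"amplitudes missing channel {ch!r}")
            for band in self.oscillator_freqs:
                for seg, a in self.amplitudes[ch].get(band, {}).items():
                    if a < 0:
                        raise ValueError(f"amplitude[{ch}][{band}][{seg}] must be >= 0")

    def amplitude(self, channel: str, band: str, segment: str) -> float:
        per_band = self.amplitudes[channel].get(band, {})
        return float(per_band.get(segment, per_band.get("quiet", 0.0)))

    @classmethod
    def from_ratio_targets(
        cls,
        ratios: Mapping[str, Mapping[str, float]],
        log_beta_power: float = 3.4,
        theta_amplitude: float = 3.0,
        pink_sd: float = 2.0,
        n_cycles: float = 7.0,
    ) -> "EegPlan":
        """Build a plan whose planted alpha/beta ratio-of-log-powers hits targets.

        ``ratios[channel][segment]`` is the target ``ln(P_alpha)/ln(P_beta)``;
        the beta oscillator amplitude is fixed by ``log_beta_power`` (natural
        log of band power in µV²) and the alpha amplitude is solved per segment.
        """
        if log_beta_power <= 0:
            raise ValueError("log_beta_power must be > 0 for a well-defined log ratio")
        bands = BandDefinition()
        freqs = {"theta": 5.5, "alpha": 10.0, "beta": 20.0}
        beta_amp = amplitude_for_band_power(
            math.exp(log_beta_power), freqs["beta"], bands["beta"], n_cycles
        )
        amplitudes: dict[str, dict[str, dict[str, float]]] = {}
        for ch in EEG_CHANNELS:
            ch_ratios = ratios.get(ch, {})
            alpha_amp = {
                seg: amplitude_for_band_power(
                    math.exp(float(ch_ratios.get(seg, 1.0)) * log_beta_power),
                    freqs["alpha"],
                    bands["alpha"],
                    n_cycles,
                )
                for seg in ENVELOPE_SEGMENTS
            }
            amplitudes[ch] = {
                "theta": {seg: theta_amplitude for seg in ENVELOPE_SEGMENTS},
                "alpha": alpha_amp,
                "beta": {seg: beta_amp for seg in ENVELOPE_SEGMENTS},
            }
        return cls(amplitudes=amplitudes, oscillator_freqs=freqs, pink_sd=pink_sd, bands=bands)


@dataclass(frozen=True)
class Timeline:
    """Absolute event times (seconds from trial start) of one planted trial."""

    apa_start: float
    movement_start: float
    flexion_end: float
    extension_start: float
    movement_end: float
    total_duration: float

    def segment_bounds(self) -> dict[str, tuple[float, float]]:
        return {
            "apa": (self.apa_start, self.movement_start),
            "flexion": (self.movement_start, self.flexion_end),
            "switch": (self.flexion_end, self.extension_start),
            "extension": (self.extension_start, self.movement_end),
        }

    @classmethod
    def from_plans(cls, kin: KinematicPlan, cop: CopPlan) -> "Timeline":
        if cop.apa_lead_time >= kin.pre_movement_hold:
            raise ValueError(
                "APA onset collides with the baseline window: "
                f"apa_lead_time={cop.apa_lead_time} s must be shorter than "
                f"pre_movement_hold={kin.pre_movement_hold} s"
            )
        t0 = kin.baseline_duration + kin.pre_movement_hold
        t_flex_end = t0 + kin.flexion_duration
        t_ext_start = t_flex_end + kin.switch_duration
        t_move_end = t_ext_start + kin.extension_duration
        return cls(
            apa_start=t0 - cop.apa_lead_time,
            movement_start=t0,
            flexion_end=t_flex_end,
            extension_start=t_ext_start,
            movement_end=t_move_end,
            total_duration=t_move_end + kin.tail_duration,
        )


@dataclass
class TrialRecording:
    """Synchronized multichannel 1 kHz recording of one trial."""

    fs: float
    angle: np.ndarray  # trunk flexion angle, degrees
    cop_ap: np.ndarray  # COP anterior-posterior position, mm (anterior positive)
    emg: dict[str, np.ndarray]  # {"ra", "es"}
    eeg: dict[str, np.ndarray]  # {"fp1", "fp2", "cz", "poz"}
    baseline_window: tuple[int, int]  # [start, end) sample indices of quiet standing
    meta: dict = field(default_factory=dict)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        n = len(self.angle)
        series = [self.cop_ap, *self.emg.values(), *self.eeg.values()]
        if any(len(s) != n for s in series):
            raise ValueError("all channels must have equal length")
        b0, b1 = self.baseline_window
        if not 0 <= b0 < b1 <= n:
            raise ValueError("baseline_window out of range")
        if (b1 - b0) / self.fs < 10.0 - 1e-9:
            raise ValueError("baseline window must span at least 10 s")
        if self.fs <= 2 * 400.0:
            raise ValueError("sampling rate must exceed twice the EMG band edge (400 Hz)")

    @property
    def n_samples(self) -> int:
        return len(self.angle)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs
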