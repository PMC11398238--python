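"""Movement-phase segmentation from angular velocity and COP onset.

Phase rules (flexion positive):

* flexion: from the first up-crossing of +15 deg/s until the velocity, after
  its flexion peak, falls back below +15 deg/s;
* switch: from the end of flexion until extension begins (velocity exceeds
  15 deg/s in the extension direction);
* extension: from that crossing until the velocity, after its extension peak,
  returns above -15 deg/s;
* APA: from the COP-AP displacement onset -- the last time the COP speed
  rises through 5% of its peak within a search window and stays above it
  until the peak -- to the start of flexion.

Crossings are located by linear interpolation between samples and reported as
the nearest integer index, ties rounding toward the phase interior.  Locating
each phase's velocity extremum *first* and then the threshold crossing after
it disambiguates jitter-induced early dips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import ProcessedTrial

__all__ = [
    "SegmentationError",
    "NoMovementError",
    "NoApaError",
    "AmbiguousTrialError",
    "PhaseSegmentation",
    "angular_velocity",
    "detect_movement_phases",
    "detect_apa_onset",
    "segment",
]


class SegmentationError(ValueError):
    """Segmentation failed on this trial."""


class NoMovementError(SegmentationError):
    """The velocity never crossed the movement threshold."""


class NoApaError(SegmentationError):
    """No anticipatory COP displacement was detected."""


class AmbiguousTrialError(SegmentationError):
    """More than one flexion-extension cycle present and no cycle selected."""


@dataclass(frozen=True)
class PhaseSegmentation:
    """Sample-index boundaries of the APA/flexion/switch/extension phases."""

    apa_onset: int
    flexion_onset: int
    flexion_offset: int
    extension_onset: int
    extension_offset: int
    fs: float
    n_samples: int

    def __post_init__(self) -> None:
        idx = (
            self.apa_onset,
            self.flexion_onset,
            self.flexion_offset,
            self.extension_onset,
            self.extension_offset,
        )
        if not (idx[0] < idx[1] <= idx[2] <= idx[3] <= idx[4]):
            raise SegmentationError(f"phase boundaries out of order: {idx}")
        if idx[0] < 0 or idx[4] > self.n_samples:
            raise SegmentationError("phase boundaries outside the recording")

    def window(self, phase: str) -> tuple[int, int]:
        return {
            "apa": (self.apa_onset, self.flexion_onset),
            "flexion": (self.flexion_onset, self.flexion_offset),
            "switch": (self.flexion_offset, self.extension_onset),
            "extension": (self.extension_onset, self.extension_offset),
        }[phase]

    def duration(self, phase: str) -> float:
        i0, i1 = self.window(phase)
        return (i1 - i0) / self.fs

    def to_dict(self) -> dict:
        return {
            "fs": self.fs,
            "indices": {
                "apa_onset": self.apa_onset,
                "flexion_onset": self.flexion_onset,
                "flexion_offset": self.flexion_offset,
                "extension_onset": self.extension_onset,
                "extension_offset": self.extension_offset,
            },
            "durations_s": {p: self.duration(p) for p in ("apa", "flexion", "switch", "extension")},
        }


def angular_velocity(angle: np.ndarray, fs: float) -> np.ndarray:
    """Central-difference angular velocity in deg/s (flexion positive)."""
    angle = np.asarray(angle, dtype=float)
    if len(angle) < 3:
        raise SegmentationError("need at least 3 samples to differentiate")
    return np.gradient(angle) * fs


def _interp_crossing(x: np.ndarray, i: int, level: float) -> float:
    """Fractional index where x crosses `level` between samples i and i+1."""
    x0, x1 = x[i], x[i + 1]
    if x1 == x0:
        return float(i)
    return i + (level - x0) / (x1 - x0)


def _round_toward(frac: float, interior: str) -> int:
    """Nearest integer index; exact .5 ties round toward the phase interior."""
    lo = math.floor(frac)
    rem = frac - lo
    if abs(rem - 0.5) < 1e-12:
        return lo + 1 if interior == "later" else lo
    return lo + 1 if rem > 0.5 else lo


def _first_up_crossing(
    x: np.ndarray, level: float, start: int, stop: int, min_run: int = 0
) -> float | None:
    """First interpolated up-crossing of `level` in [start, stop).

    ``min_run`` samples must stay at or above the level after the crossing
    (guard against jitter-induced micro-phases).
    """
    below = x[start : stop - 1] < level
    above = x[start + 1 : stop] >= level
    for i in np.flatnonzero(below & above):
        j = start + int(i)
        if min_run > 1:
            run = x[j + 1 : min(j + 1 + min_run, len(x))]
            if not np.all(run >= level):
                continue
        return _interp_crossing(x, j, level)
    return None


def _first_down_crossing(x: np.ndarray, level: float, start: int, stop: int) -> float | None:
    above = x[start : stop - 1] >= level
    below = x[start + 1 : stop] < level
    hits = np.flatnonzero(above & below)
    if len(hits) == 0:
        return None
    return _interp_crossing(x, start + int(hits[0]), level)


def detect_movement_phases(
    velocity: np.ndarray,
    fs: float,
    v_thresh: float = 15.0,
    min_duration: float = 0.05,
    allow_multiple_cycles: bool = False,
) -> tuple[int, int, int, int]:
    """Flexion/switch/extension boundaries from the velocity threshold rule.

    Returns ``(flexion_onset, flexion_offset, extension_onset,
    extension_offset)`` sample indices.  ``min_duration`` (seconds) is the
    minimum above-threshold run accepted at an onset; set 0 for the strict
    literal rule.
    """
    v = np.asarray(velocity, dtype=float)
    n = len(v)
    if v_thresh <= 0:
        raise ValueError("v_thresh must be > 0")
    min_run = int(round(min_duration * fs))

    i_peak_flex = int(np.argmax(v))
    if v[i_peak_flex] < v_thresh:
        raise NoMovementError(
            f"no movement detected: peak flexion velocity {v[i_peak_flex]:.2f} deg/s "
            f"never exceeded {v_thresh} deg/s"
        )
    c_on = _first_up_crossing(v, v_thresh, 0, i_peak_flex + 1, min_run)
    if c_on is None:
        raise NoMovementError("no flexion onset crossing found before the velocity peak")
    flexion_onset = _round_toward(c_on, "later")

    c_off = _first_down_crossing(v, v_thresh, i_peak_flex, n)
    if c_off is None:
        raise NoMovementError("flexion velocity never fell back below the threshold")
    flexion_offset = _round_toward(c_off, "earlier")

    # crossing of -v up through +thresh == v down through -thresh
    ext_on_frac = _first_up_crossing(-v, v_thresh, flexion_offset, n, min_run)
    if ext_on_frac is None:
        raise NoMovementError("no extension movement detected after flexion")
    extension_onset = _round_toward(ext_on_frac, "later")

    i_peak_ext = extension_onset + int(np.argmin(v[extension_onset:]))
    c_ext_off = _first_down_crossing(-v, v_thresh, i_peak_ext, n)
    if c_ext_off is None:
        raise NoMovementError("extension velocity never returned above -threshold")
    extension_offset = _round_toward(c_ext_off, "earlier")

    if not allow_multiple_cycles:
        extra = _first_up_crossing(v, v_thresh, extension_offset, n, min_run)
        if extra is not None:
            raise AmbiguousTrialError(
                "ambiguous trial: a further flexion cycle begins near sample "
                f"{int(extra)}; pass allow_multiple_cycles=True or pre-crop the trial"
            )
    return flexion_onset, flexion_offset, extension_onset, extension_offset


def detect_apa_onset(
    cop_f: np.ndarray,
    fs: float,
    flexion_onset: int,
    fraction: float = 0.05,
    search_window: float = 2.0,
    min_peak_speed: float = 1e-6,
) -> int:
    """COP displacement onset: `fraction` of peak COP speed before flexion.

    The COP speed ``|d(cop)/dt|`` is evaluated in a window of
    ``search_window`` seconds ending at ``flexion_onset``; the onset is the
    last sample before the in-window speed peak at which the speed rises
    through ``fraction`` of that peak and stays above it until the peak.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    cop = np.asarray(cop_f, dtype=float)
    w0 = max(0, flexion_onset - int(round(search_window * fs)))
    if flexion_onset - w0 < 3:
        raise NoApaError("COP search window before flexion onset is empty")
    speed = np.abs(np.gradient(cop[w0 : flexion_onset + 1]) * fs)
    i_peak = int(np.argmax(speed))
    peak = speed[i_peak]
    if peak <= min_peak_speed:
        raise NoApaError("no APA detected: COP is flat before flexion onset")
    level = fraction * peak
    below = np.flatnonzero(speed[:i_peak] < level)
    if len(below) == 0:
        raise NoApaError(
            f"APA onset not found: COP speed already above {fraction:.0%} of its peak "
            f"({peak:.3g} mm/s) at the start of the {search_window} s search window"
        )
    j = int(below[-1])  # last sub-threshold sample before the peak
    onset = _round_toward(_interp_crossing(speed, j, level), "later")
    apa_onset = w0 + onset
    if apa_onset >= flexion_onset:
        raise NoApaError("detected APA onset does not precede flexion onset")
    return apa_onset


def segment(
    processed: ProcessedTrial,
    v_thresh: float = 15.0,
    cop_onset_fraction: float = 0.05,
    apa_search_window: float = 2.0,
    min_duration: float = 0.05,
) -> PhaseSegmentation:
    """Full five-boundary segmentation of one processed trial."""
    try:
        velocity = angular_velocity(processed.angle_f, processed.fs)
        fo, fx, eo, ex = detect_movement_phases(
            velocity, processed.fs, v_thresh=v_thresh, min_duration=min_duration
        )
        apa = detect_apa_onset(
            processed.cop_f,
            processed.fs,
            fo,
            fraction=cop_onset_fraction,
            search_window=apa_search_window,
        )
    except SegmentationError as err:
        trial_id = processed.meta or "unlabelled trial"
        raise type(err)(f"{err} [trial: {trial_id}]") from err
    return PhaseSegmentation(
        apa_onset=apa,
        flexion_onset=fo,
        flexion_offset=fx,
        extension_onset=eo,
        extension_offset=ex,
        fs=processed.fs,
        n_samples=processed.n_samples,
    )
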