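"""Pipeline configuration: every tunable constant in one serializable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .synth import CohortConfig, ParamSpec

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Cohort, filtering, segmentation, wavelet and statistics settings."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    # preprocessing
    kinematic_cutoff_hz: float = 6.0
    emg_band_hz: tuple[float, float] = (10.0, 400.0)
    emg_envelope_cutoff_hz: float | None = 6.0
    eeg_band_hz: tuple[float, float] = (1.0, 30.0)
    filter_order: int = 4
    # segmentation
    v_thresh: float = 15.0  # deg/s
    cop_onset_fraction: float = 0.05
    apa_search_window_s: float = 2.0
    min_phase_duration_s: float = 0.05
    # wavelet
    n_cycles: float = 7.0
    freq_step_hz: float = 1.0
    # statistics
    n_trees: int = 500
    k: int = 10
    alpha: float = 0.05
    analysis_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cop_onset_fraction < 1:
            raise ValueError("cop_onset_fraction must lie in (0, 1)")
        if min(self.v_thresh, self.kinematic_cutoff_hz, self.n_cycles, self.alpha) <= 0:
            raise ValueError("thresholds must be positive")
        if self.k <= 0 or self.n_trees <= 0:
            raise ValueError("k and n_trees must be positive")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["params"] = {
            name: {
                "median": spec.median,
                "iqr": list(spec.iqr),
                "median_novision": spec.median_novision,
                "within_frac": spec.within_frac,
                "lo": None if spec.lo == float("-inf") else spec.lo,
                "hi": None if spec.hi == float("inf") else spec.hi,
            }
            for name, spec in self.cohort.params.items()
        }
        d["emg_band_hz"] = list(self.emg_band_hz)
        d["eeg_band_hz"] = list(self.eeg_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort_d = dict(d.pop("cohort", {}))
        params_d = cohort_d.pop("params", None)
        cohort = CohortConfig(**cohort_d) if params_d is None else CohortConfig(
            **cohort_d,
            params={
                name: ParamSpec(
                    median=s["median"],
                    iqr=tuple(s["iqr"]),
                    median_novision=s.get("median_novision"),
                    within_frac=s.get("within_frac", 0.3),
                    lo=float("-inf") if s.get("lo") is None else s["lo"],
                    hi=float("inf") if s.get("hi") is None else s["hi"],
                )
                for name, s in params_d.items()
            },
        )
        if "emg_band_hz" in d:
            d["emg_band_hz"] = tuple(d["emg_band_hz"])
        if "eeg_band_hz" in d:
            d["eeg_band_hz"] = tuple(d["eeg_band_hz"])
        return cls(cohort=cohort, **d)

    def to_yaml(self, path: Path | str | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, cohort=replace(self.cohort, seed=int(seed)), analysis_seed=int(seed))
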