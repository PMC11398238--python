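"""EEG frequency bands and Morlet band-power conventions.

The continuous Morlet transform used throughout the package is the complex
Morlet ("cmor") wavelet with an ``n_cycles`` time-domain width, i.e. a
Gaussian spectral response of standard deviation ``sigma_f = f / n_cycles``
around each analysis frequency ``f``.  Band power is defined as the mean,
over a 1 Hz analysis grid spanning the band, of the per-frequency power
``S(f)``, where ``S(f)`` is calibrated so that a pure sinusoid of amplitude
``a`` at frequency ``f`` contributes ``a**2 / 2`` (its physical mean power).
With this convention a tone observed at an off-centre analysis frequency is
attenuated by the squared Gaussian response
``exp(-(f0 - f)**2 / sigma_f**2)``.

Both the feature extractor and the synthetic generator import these
conventions, so planted band amplitudes are recoverable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BandDefinition",
    "BANDS",
    "band_frequency_grid",
    "tone_band_gain",
    "amplitude_for_band_power",
    "morlet_wavelet_name",
]

#: default number of wavelet cycles (time-frequency trade-off)
DEFAULT_N_CYCLES = 7.0

#: default spacing of the analysis-frequency grid, Hz
DEFAULT_FREQ_STEP = 1.0


@dataclass(frozen=True)
class BandDefinition:
    """Canonical theta/alpha/beta band edges in Hz."""

    theta: tuple[float, float] = (4.0, 7.0)
    alpha: tuple[float, float] = (8.0, 12.0)
    beta: tuple[float, float] = (13.0, 30.0)

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for name in ("theta", "alpha", "beta"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"band {name} has non-positive width: {(lo, hi)}")
            if lo < prev_hi:
                raise ValueError("bands must be non-overlapping and ordered")
            prev_hi = hi

    def __getitem__(self, name: str) -> tuple[float, float]:
        return getattr(self, name)

    def names(self) -> tuple[str, ...]:
        return ("theta", "alpha", "beta")


BANDS = BandDefinition()


def band_frequency_grid(
    band: tuple[float, float], step: float = DEFAULT_FREQ_STEP
) -> np.ndarray:
    """Analysis frequencies covering ``band`` inclusively at spacing ``step``."""
    lo, hi = band
    return np.arange(lo, hi + 1e-9, step)


def morlet_wavelet_name(n_cycles: float = DEFAULT_N_CYCLES) -> str:
    """pywt wavelet string for an ``n_cycles`` complex Morlet.

    pywt's ``cmorB-C`` wavelet is ``(pi*B)**-0.5 * exp(-t**2/B) * exp(2j*pi*C*t)``;
    matching its Gaussian envelope to the ``sigma_t = n_cycles / (2*pi*f)``
    convention with centre frequency C = 1 gives ``B = n_cycles**2 / (2*pi**2)``.
    """
    b = n_cycles**2 / (2.0 * np.pi**2)
    return f"cmor{b:.10f}-1.0"


def tone_band_gain(
    f0: float,
    band: tuple[float, float],
    n_cycles: float = DEFAULT_N_CYCLES,
    step: float = DEFAULT_FREQ_STEP,
) -> float:
    """Band-mean squared Morlet response to a tone at ``f0``.

    A tone of amplitude ``a`` at ``f0`` yields band power
    ``(a**2 / 2) * tone_band_gain(f0, band)``.
    """
    freqs = band_frequency_grid(band, step)
    sigma = freqs / n_cycles
    return float(np.mean(np.exp(-((f0 - freqs) ** 2) / sigma**2)))


def amplitude_for_band_power(
    power: float,
    f0: float,
    band: tuple[float, float],
    n_cycles: float = DEFAULT_N_CYCLES,
    step: float = DEFAULT_FREQ_STEP,
) -> float:
    """Tone amplitude at ``f0`` that produces the requested band power."""
    if power < 0:
        raise ValueError("band power must be non-negative")
    g = tone_band_gain(f0, band, n_cycles, step)
    return float(np.sqrt(2.0 * power / g))
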