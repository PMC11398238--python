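"""Feature extraction: planted-value recovery, CCI algebra, band powers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram

from posturekit.bands import BANDS, amplitude_for_band_power
from posturekit.features import (
    FEATURE_NAMES,
    FeatureError,
    aggregate_subject,
    alpha_beta_ratio,
    cci,
    cop_features,
    emg_phase_means,
    morlet_band_power,
)
from posturekit.pipeline import extract_trial_features
from posturekit.plans import CopPlan, EmgPlan, KinematicPlan
from posturekit.segment import PhaseSegmentation
from posturekit.synth import generate_trial

FS = 1000.0


@pytest.fixture(scope="module")
def extracted(noise_free_trial, pipeline_config):
    return extract_trial_features(noise_free_trial, pipeline_config)


class TestKinematicAndCopRecovery:
    def test_planted_peak_angle_recovered(self, extracted):
        assert extracted["max_flexion_angle"] == pytest.approx(48.8, rel=0.01)

    def test_planted_peak_velocity_recovered(self, pipeline_config):
        rec = generate_trial(
            KinematicPlan(peak_angle=49.0, peak_flex_velocity=80.5), CopPlan(), seed=1
        )
        feats = extract_trial_features(rec, pipeline_config)
        assert feats["max_flexion_velocity"] == pytest.approx(80.5, rel=0.01)

    def test_planted_extension_velocity_recovered(self, extracted):
        assert extracted["max_extension_velocity"] == pytest.approx(70.0, rel=0.01)

    def test_planted_cop_displacements_recovered(self, extracted):
        assert extracted["max_cop_apa"] == pytest.approx(7.0, rel=0.02)
        assert extracted["max_cop_flexion"] == pytest.approx(47.4, rel=0.02)

    def test_recovery_sweep_over_random_plans(self, pipeline_config):
        """Planted kinematic/COP parameters recovered within 2% across plans."""
        rng = np.random.default_rng(12)
        for _ in range(15):
            kin = KinematicPlan(
                peak_angle=float(rng.uniform(35, 60)),
                peak_flex_velocity=float(rng.uniform(60, 110)),
                peak_ext_velocity=float(rng.uniform(50, 90)),
            )
            cop = CopPlan(
                apa_amplitude=float(rng.uniform(4, 11)),
                flexion_displacement=float(rng.uniform(30, 65)),
            )
            feats = extract_trial_features(generate_trial(kin, cop, seed=3), pipeline_config)
            assert feats["max_flexion_angle"] == pytest.approx(kin.peak_angle, rel=0.01)
            assert feats["max_flexion_velocity"] == pytest.approx(kin.peak_flex_velocity, rel=0.01)
            assert feats["max_cop_apa"] == pytest.approx(cop.apa_amplitude, rel=0.02)
            assert feats["max_cop_flexion"] == pytest.approx(cop.flexion_displacement, rel=0.02)

    def test_flat_cop_with_forced_segmentation_gives_zero(self):
        seg = PhaseSegmentation(
            apa_onset=1000, flexion_onset=1300, flexion_offset=2000,
            extension_onset=2500, extension_offset=3200, fs=FS, n_samples=5000,
        )
        out = cop_features(np.zeros(5000), seg)
        assert out["max_cop_apa"] == 0.0 and out["max_cop_flexion"] == 0.0


class TestEmgFeatures:
    def test_constant_envelope_means_100(self):
        seg = PhaseSegmentation(
            apa_onset=100, flexion_onset=400, flexion_offset=900,
            extension_onset=1400, extension_offset=2000, fs=FS, n_samples=2500,
        )
        env = {m: np.full(2500, 100.0) for m in ("ra", "es")}
        means = emg_phase_means(env, seg)
        assert all(v == pytest.approx(100.0) for v in means.values())

    def test_envelope_doubling_doubles_means(self):
        seg = PhaseSegmentation(
            apa_onset=100, flexion_onset=400, flexion_offset=900,
            extension_onset=1400, extension_offset=2000, fs=FS, n_samples=2500,
        )
        rng = np.random.default_rng(0)
        env = {m: rng.uniform(10, 300, 2500) for m in ("ra", "es")}
        doubled = {m: 2 * x for m, x in env.items()}
        a, b = emg_phase_means(env, seg), emg_phase_means(doubled, seg)
        for key in a:
            assert b[key] == pytest.approx(2 * a[key])

    def test_planted_es_gain_monte_carlo(self, pipeline_config):
        """A planted flexion-phase gain of 6.45 is recovered near 645%."""
        gains = {
            "ra": {"quiet": 1.0, "apa": 1.5, "flexion": 1.3, "switch": 1.1, "extension": 1.8},
            "es": {"quiet": 1.0, "apa": 6.45, "flexion": 6.45, "switch": 2.0, "extension": 4.5},
        }
        vals = []
        for seed in range(6):
            rec = generate_trial(
                KinematicPlan(), CopPlan(), EmgPlan(burst_gains=gains, noise_sd=0.0), seed=seed
            )
            vals.append(extract_trial_features(rec, pipeline_config)["es_mean_flexion"])
        assert np.mean(vals) == pytest.approx(645.0, rel=0.05)


class TestCci:
    def test_printed_formula_values(self):
        assert cci(np.array([100.0]), np.array([100.0]))[0] == pytest.approx(1.0)
        assert cci(np.array([100.0]), np.array([300.0]))[0] == pytest.approx(0.5)
        assert cci(np.array([0.0]), np.array([500.0]))[0] == 0.0

    def test_double_zero_policies(self):
        z = np.array([0.0])
        assert cci(z, z, zero_policy="zero")[0] == 0.0
        assert np.isnan(cci(z, z, zero_policy="exclude")[0])

    @settings(derandomize=True, max_examples=200)
    @given(
        ra=st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
        es=st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
    )
    def test_symmetry_and_bounds(self, ra, es):
        a = cci(np.array([ra]), np.array([es]))[0]
        b = cci(np.array([es]), np.array([ra]))[0]
        assert a == b
        assert 0.0 <= a <= 1.0
        if ra == es and ra > 0:
            assert a == pytest.approx(1.0)

    def test_negative_envelope_rejected(self):
        with pytest.raises(FeatureError, match="non-negative"):
            cci(np.array([-1.0]), np.array([1.0]))

    def test_phase_means_within_bounds(self, noise_free_trial, pipeline_config):
        feats = extract_trial_features(noise_free_trial, pipeline_config)
        for phase in ("apa", "flexion", "switch", "extension"):
            assert 0.0 <= feats[f"cci_mean_{phase}"] <= 1.0


class TestBandPower:
    WIN = (2000, 6000)

    @staticmethod
    def _tone(amp: float, freq: float, n: int = 8000) -> np.ndarray:
        t = np.arange(n) / FS
        return amp * np.cos(2 * np.pi * freq * t + 0.7)

    def test_amplitude_doubling_adds_ln4(self):
        lo = morlet_band_power(self._tone(5.0, 10.0), FS, self.WIN, BANDS["alpha"])
        hi = morlet_band_power(self._tone(10.0, 10.0), FS, self.WIN, BANDS["alpha"])
        assert hi - lo == pytest.approx(math.log(4.0), rel=0.05)

    @pytest.mark.parametrize("freq,band", [(10.0, "alpha"), (20.0, "beta")])
    def test_agrees_with_periodogram_oracle(self, freq, band):
        """Independent FFT route: periodogram integrated against the Morlet response."""
        x = self._tone(8.0, freq)
        wavelet = math.exp(morlet_band_power(x, FS, self.WIN, BANDS[band]))
        f, pxx = periodogram(x[self.WIN[0] : self.WIN[1]], FS, scaling="spectrum")
        grid = np.arange(BANDS[band][0], BANDS[band][1] + 1e-9, 1.0)
        oracle = np.mean([np.sum(pxx * np.exp(-((f - fa) ** 2) / (fa / 7.0) ** 2)) for fa in grid])
        assert wavelet == pytest.approx(oracle, rel=0.10)

    def test_zero_signal_hits_guarded_floor(self):
        out = morlet_band_power(np.zeros(8000), FS, self.WIN, BANDS["alpha"])
        assert out == pytest.approx(math.log(1e-12))

    def test_window_too_short_names_constraint(self):
        with pytest.raises(FeatureError, match="2 cycles of 8.0 Hz"):
            morlet_band_power(np.zeros(8000), FS, (2000, 2100), BANDS["alpha"])

    def test_in_band_monotonicity(self):
        amps = [2.0, 4.0, 8.0, 16.0]
        powers = [
            morlet_band_power(self._tone(a, 10.0), FS, self.WIN, BANDS["alpha"]) for a in amps
        ]
        assert all(b > a for a, b in zip(powers, powers[1:]))


class TestAlphaBetaRatio:
    @staticmethod
    def _channel(ratio: float, n: int = 20000, log_beta: float = 3.4) -> np.ndarray:
        t = np.arange(n) / FS
        a_alpha = amplitude_for_band_power(math.exp(ratio * log_beta), 10.0, BANDS["alpha"])
        a_beta = amplitude_for_band_power(math.exp(log_beta), 20.0, BANDS["beta"])
        return a_alpha * np.cos(2 * np.pi * 10.0 * t) + a_beta * np.cos(2 * np.pi * 20.0 * t + 1.1)

    @staticmethod
    def _seg() -> PhaseSegmentation:
        return PhaseSegmentation(
            apa_onset=2000, flexion_onset=4000, flexion_offset=8000,
            extension_onset=12000, extension_offset=16000, fs=FS, n_samples=20000,
        )

    def test_equal_band_powers_give_unit_ratio(self):
        eeg = {ch: self._channel(1.0) for ch in ("fp1", "fp2", "cz", "poz")}
        out = alpha_beta_ratio(eeg, self._seg())
        for phase in ("apa", "flexion", "switch", "extension"):
            assert out[f"ab_ratio_poz_{phase}"] == pytest.approx(1.0, abs=0.05)

    def test_fp_is_mean_of_fp1_fp2_ratios(self):
        eeg = {
            "fp1": self._channel(0.8),
            "fp2": self._channel(1.2),
            "cz": self._channel(1.0),
            "poz": self._channel(1.0),
        }
        out = alpha_beta_ratio(eeg, self._seg())
        assert out["ab_ratio_fp_flexion"] == pytest.approx(1.0, abs=0.05)

    def test_alpha_dominance_raises_ratio(self, pipeline_config):
        base = alpha_beta_ratio({ch: self._channel(1.0) for ch in ("fp1", "fp2", "cz", "poz")}, self._seg())
        loud = alpha_beta_ratio({ch: self._channel(1.4) for ch in ("fp1", "fp2", "cz", "poz")}, self._seg())
        assert loud["ab_ratio_cz_switch"] > base["ab_ratio_cz_switch"]


class TestAssembleAndAggregate:
    def test_exactly_29_features_in_order(self, extracted):
        assert list(extracted) == list(FEATURE_NAMES)
        assert len(extracted) == 29

    def test_identical_trials_identical_vectors(self, default_plans, pipeline_config):
        kin, cop = default_plans
        a = extract_trial_features(generate_trial(kin, cop, seed=5), pipeline_config)
        b = extract_trial_features(generate_trial(kin, cop, seed=5), pipeline_config)
        assert a == b

    def test_csv_round_trip_bit_identical(self, extracted, tmp_path):
        from posturekit.io import read_feature_table, write_feature_table

        frame = pd.DataFrame([{"subject": 1, "condition": "vision", **extracted}])
        write_feature_table(frame, tmp_path / "features.csv")
        back = read_feature_table(tmp_path / "features.csv")
        for name in FEATURE_NAMES:
            assert back[name].iloc[0] == extracted[name]

    def test_aggregate_identity_and_mean(self):
        v = {name: float(i) for i, name in enumerate(FEATURE_NAMES)}
        assert aggregate_subject([v, v, v]) == v
        shifted = [{k: val + d for k, val in v.items()} for d in (0.0, 10.0, 20.0)]
        agg = aggregate_subject(shifted)
        assert agg[FEATURE_NAMES[0]] == pytest.approx(10.0)

    def test_aggregate_median_differs_only_when_trials_differ(self):
        v = {name: 1.0 for name in FEATURE_NAMES}
        assert aggregate_subject([v, v], how="median") == aggregate_subject([v, v], how="mean")
        w = [{k: x for k in v} for x in (1.0, 2.0, 10.0)]
        assert aggregate_subject(w, how="median")[FEATURE_NAMES[0]] == 2.0
        assert aggregate_subject(w, how="mean")[FEATURE_NAMES[0]] == pytest.approx(13.0 / 3)

    def test_empty_aggregate_rejected(self):
        with pytest.raises(FeatureError):
            aggregate_subject([])
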