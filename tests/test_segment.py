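"""Phase detection against closed-form crossing times and invariances."""

import math

import numpy as np
import pytest

from posturekit.plans import CopPlan, KinematicPlan, Timeline
from posturekit.preprocess import ProcessedTrial, process_trial
from posturekit.segment import (
    AmbiguousTrialError,
    NoApaError,
    NoMovementError,
    PhaseSegmentation,
    SegmentationError,
    angular_velocity,
    detect_apa_onset,
    detect_movement_phases,
    segment,
)
from posturekit.synth import cop_profile, generate_trial

FS = 1000.0


def _identity_processed(rec) -> ProcessedTrial:
    """Wrap raw channels unfiltered, to probe the detectors in isolation."""
    return ProcessedTrial(
        fs=rec.fs,
        angle_f=rec.angle.astype(float),
        cop_f=rec.cop_ap.astype(float),
        emg_env={m: np.abs(x) for m, x in rec.emg.items()},
        eeg_f=dict(rec.eeg),
        baseline_window=rec.baseline_window,
        meta=rec.meta,
    )


class TestAngularVelocity:
    def test_constant_angle_zero_velocity(self):
        assert np.all(angular_velocity(np.full(100, 12.0), FS) == 0.0)

    def test_linear_ramp_exact(self):
        t = np.arange(2000) / FS
        v = angular_velocity(10.0 * t, FS)
        assert v[1:-1] == pytest.approx(10.0, abs=1e-9)

    def test_raised_cosine_peak_closed_form(self):
        a, T = 48.8, 0.958
        t = np.arange(int(T * FS) + 1) / FS
        theta = a / 2 * (1 - np.cos(np.pi * t / T))
        peak = np.max(angular_velocity(theta, FS))
        assert peak == pytest.approx(a * np.pi / (2 * T), rel=1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(SegmentationError):
            angular_velocity(np.array([1.0, 2.0]), FS)


class TestMovementPhases:
    def test_sine_cycle_analytic_crossings(self):
        """v = 100 sin(pi t) on [0, 2] s: crossings at asin(0.15)/pi from each end."""
        t = np.arange(int(2.0 * FS) + 1) / FS
        v = 100.0 * np.sin(np.pi * t)
        fo, fx, eo, ex = detect_movement_phases(v, FS)
        d = math.asin(15.0 / 100.0) / math.pi  # 0.04792 s
        assert fo == pytest.approx(d * FS, abs=1)
        assert fx == pytest.approx((1.0 - d) * FS, abs=1)
        assert eo == pytest.approx((1.0 + d) * FS, abs=1)
        assert ex == pytest.approx((2.0 - d) * FS, abs=1)
        # symmetric profile: equal flexion and extension durations
        assert abs((fx - fo) - (ex - eo)) <= 2

    def test_subthreshold_velocity_raises(self):
        t = np.arange(2000) / FS
        with pytest.raises(NoMovementError, match="no movement"):
            detect_movement_phases(10.0 * np.sin(np.pi * t), FS)

    def test_second_cycle_flagged_ambiguous(self):
        t = np.arange(int(4.0 * FS)) / FS
        v = 100.0 * np.sin(np.pi * t)  # two full flexion-extension cycles
        with pytest.raises(AmbiguousTrialError):
            detect_movement_phases(v, FS)
        detect_movement_phases(v, FS, allow_multiple_cycles=True)

    def test_threshold_equivariance(self):
        t = np.arange(int(2.0 * FS) + 1) / FS
        v = 100.0 * np.sin(np.pi * t)
        assert detect_movement_phases(v, FS, v_thresh=15.0) == detect_movement_phases(
            3.0 * v, FS, v_thresh=45.0
        )


class TestApaOnset:
    def test_raised_cosine_analytic_crossing(self, default_plans, timeline):
        """Onset at t0 + (T_a/pi) asin(0.05) for a raised-cosine APA shift."""
        _, cop_plan = default_plans
        cop = cop_profile(cop_plan, timeline, FS)
        flexion_onset = int(round((timeline.movement_start + 0.06) * FS))
        onset = detect_apa_onset(cop, FS, flexion_onset)
        expected = timeline.apa_start + (cop_plan.apa_lead_time / math.pi) * math.asin(0.05)
        assert onset == pytest.approx(expected * FS, abs=2)

    def test_flat_cop_raises(self):
        with pytest.raises(NoApaError, match="flat"):
            detect_apa_onset(np.zeros(5000), FS, 4000)

    def test_onset_precedes_flexion_over_random_plans(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            kin = KinematicPlan(
                peak_angle=float(rng.uniform(30, 60)),
                peak_flex_velocity=float(rng.uniform(50, 120)),
            )
            cop_plan = CopPlan(
                apa_amplitude=float(rng.uniform(2, 12)),
                flexion_displacement=float(rng.uniform(20, 70)),
                apa_lead_time=float(rng.uniform(0.15, 0.6)),
            )
            tl = Timeline.from_plans(kin, cop_plan)
            cop = cop_profile(cop_plan, tl, FS)
            v_peak = kin.peak_flex_velocity
            d = (kin.flexion_duration / math.pi) * math.asin(min(1.0, 15.0 / v_peak))
            flexion_onset = int(round((tl.movement_start + d) * FS))
            onset = detect_apa_onset(cop, FS, flexion_onset)
            assert onset < flexion_onset


class TestSegmentComposition:
    def test_boundaries_match_planted_timings_unfiltered(self, noise_free_trial, default_plans, timeline):
        """All five boundaries within 2 samples of the analytic crossing times."""
        kin, cop_plan = default_plans
        seg = segment(_identity_processed(noise_free_trial))
        d_f = (kin.flexion_duration / math.pi) * math.asin(15.0 / kin.peak_flex_velocity)
        d_e = (kin.extension_duration / math.pi) * math.asin(15.0 / kin.peak_ext_velocity)
        d_apa = (cop_plan.apa_lead_time / math.pi) * math.asin(0.05)
        expected = {
            "apa_onset": (timeline.apa_start + d_apa) * FS,
            "flexion_onset": (timeline.movement_start + d_f) * FS,
            "flexion_offset": (timeline.flexion_end - d_f) * FS,
            "extension_onset": (timeline.extension_start + d_e) * FS,
            "extension_offset": (timeline.movement_end - d_e) * FS,
        }
        for name, exp in expected.items():
            assert getattr(seg, name) == pytest.approx(exp, abs=2), name

    def test_switch_duration_with_analytic_tail_correction(self, noise_free_trial, default_plans):
        kin, _ = default_plans
        seg = segment(_identity_processed(noise_free_trial))
        d_f = (kin.flexion_duration / math.pi) * math.asin(15.0 / kin.peak_flex_velocity)
        d_e = (kin.extension_duration / math.pi) * math.asin(15.0 / kin.peak_ext_velocity)
        expected = kin.switch_duration + d_f + d_e  # crossings shave sub-threshold tails
        assert seg.duration("switch") == pytest.approx(expected, abs=0.005)

    def test_filtered_chain_velocity_boundaries_close(self, noise_free_trial, default_plans, timeline):
        """The 6 Hz zero-phase filter moves velocity crossings by < 5 ms."""
        kin, _ = default_plans
        seg = segment(process_trial(noise_free_trial))
        d_f = (kin.flexion_duration / math.pi) * math.asin(15.0 / kin.peak_flex_velocity)
        assert seg.flexion_onset == pytest.approx((timeline.movement_start + d_f) * FS, abs=5)
        assert seg.apa_onset < seg.flexion_onset

    def test_time_shift_equivariance(self, noise_free_trial):
        k = 250
        base = _identity_processed(noise_free_trial)
        shifted = ProcessedTrial(
            fs=base.fs,
            angle_f=np.concatenate([np.zeros(k), base.angle_f]),
            cop_f=np.concatenate([np.zeros(k), base.cop_f]),
            emg_env={m: np.concatenate([x[:k], x]) for m, x in base.emg_env.items()},
            eeg_f={c: np.concatenate([x[:k], x]) for c, x in base.eeg_f.items()},
            baseline_window=(0, base.baseline_window[1] + k),
            meta=base.meta,
        )
        a, b = segment(base), segment(shifted)
        for name in ("apa_onset", "flexion_onset", "flexion_offset", "extension_onset", "extension_offset"):
            assert getattr(b, name) - getattr(a, name) == k

    def test_ordering_invariant_enforced(self):
        with pytest.raises(SegmentationError, match="out of order"):
            PhaseSegmentation(
                apa_onset=100, flexion_onset=90, flexion_offset=200,
                extension_onset=300, extension_offset=400, fs=FS, n_samples=1000,
            )

    def test_error_carries_trial_context(self, default_plans):
        kin = KinematicPlan(peak_angle=0.5)  # movement far below 15 deg/s
        rec = generate_trial(kin, default_plans[1], seed=0, meta={"id": "weak-trial"})
        with pytest.raises(NoMovementError, match="weak-trial"):
            segment(_identity_processed(rec))
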