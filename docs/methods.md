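# Methods

This note records the model underlying `posturekit`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that matter for reproducing its outputs.

## Task and measurement model

One trial is a standing trunk flexion–extension movement: ≥10 s of quiet
standing (the normalization baseline), a short hold, a single flexion to the
maximal angle, a switch interval, and an extension back to upright. Eight
channels are synchronized at 1 kHz: trunk flexion angle (degrees, flexion
positive), COP-AP position (mm, anterior positive), RA and ES surface EMG,
and EEG at Fp1, Fp2, Cz, POz. A cohort is a paired two-condition design —
every subject performs the task with vision and without — with three trials
per subject-condition; the default cohort has 35 subjects.

## Synthetic generator

The generator's purpose is ground truth, not biomechanical realism.

* **Kinematics** are raised-cosine per segment:
  θ(t) = A/2·(1 − cos(πt/T_f)) during flexion with T_f = πA/(2·v_flex), a
  plateau at A for the switch duration, and the mirrored profile for
  extension. The raised cosine was chosen because its peak velocity has the
  closed form v = πA/(2T), so both the peak angle and the peak velocities
  are planted exactly. No published trajectory shape exists for this task;
  any smooth unimodal profile would serve, but only this one gives exact
  closed-form planting of both quantities at once.
* **COP-AP** is raised-cosine per segment as well: a posterior excursion of
  amplitude D starting `apa_lead_time` (default 0.3 s) before movement
  onset and peaking exactly at onset, an anterior excursion reaching exactly
  F at peak flexion, a hold through the switch, and a return to baseline
  during extension. The 5 %-of-peak-speed onset criterion then has the
  closed-form crossing time t₀ + (T_a/π)·asin(0.05), the oracle used by the
  segmentation tests.
* **EMG** is amplitude-modulated Gaussian noise. A Gaussian carrier of
  standard deviation σ has rectified mean σ·√(2/π), so per-phase envelope
  gains are planted exactly in expectation; normalized phase means are
  `100·gain` %. No motor-unit structure is simulated — only the envelope
  expectations matter downstream.
* **EEG** is a sum of per-phase-enveloped oscillators at 5.5 / 10 / 20 Hz
  (inside the θ 4–7, α 8–12, β 13–30 Hz bands) plus pink (1/f) noise, which
  makes band extraction non-trivial. Amplitudes are solved from target
  log-band-powers through the same Morlet band-power convention the feature
  extractor uses, so planted α/β ratios are recoverable by construction.

**Trial length.** Total duration derives from the plan segments
(10 s baseline + 2 s hold + movement + 2 s tail ≈ 16–17 s). Every extracted
feature lives inside the baseline or the movement phases, so longer
recordings add no information; all durations are configurable.

**Cohort parameters.** Each planted parameter has a vision-condition median
and IQR (normal, σ = IQR/1.349) taken from the group statistics of the
underlying study where reported, and a no-vision median encoding the
reported effect direction: −2.2° peak angle, +9.2°/s peak flexion velocity,
−12.4 mm anterior COP excursion, −0.4 mm APA excursion, ≈−10 % EMG gains
(null effects), +0.1 in the POz α/β ratio for APA and switch and the Fp
ratio in extension. A subject's baseline is drawn once and shifted by the
condition effect, preserving pairing; per-trial scatter is
N(0, within_frac·σ). The within-subject fractions are per-parameter
(0.15 for the angle up to 2.0 for the APA COP and some EEG ratios), chosen
once so that at n = 35 the planted design reproduces the qualitative
significance pattern of the underlying comparisons: kinematic and anterior
COP effects strongly significant, the switch-phase POz ratio marginal, EMG /
CCI / APA-COP comparisons null. A single global fraction cannot satisfy all
of those simultaneously.

**Planted CCI.** The cohort's ground-truth CCI per phase is derived from the
planted RA/ES gains via 2·min/(min+max) rather than drawn independently,
keeping the planted table consistent with what the signal route produces.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: multi-segment trunk dynamics, EMG motor-unit
statistics and cross-talk, volume conduction and EEG artifacts (blinks,
movement), electrode noise nonstationarity, and any dependence between
kinematic and neural parameters beyond the planted condition shifts.
Recovery results certify the *analysis chain*, not the physiology.

## Preprocessing

All filters are Butterworth second-order-section cascades applied
forward–backward (`sosfiltfilt`): offline analysis permits zero-phase
filtering, and phase alignment across modalities is required because
features are indexed by boundaries detected on the kinematic channel. The
effective order is therefore twice the design order; provenance records the
design order (4). SOS form keeps the 1 Hz EEG edge stable at 1 kHz.

The EMG chain band-passes 10–400 Hz, rectifies, smooths with a 6 Hz
low-pass (same cutoff as the kinematic channel; phase means are insensitive
to this choice, and `envelope_cutoff=None` yields the raw rectified
alternative), clips the negligible negative ringing of the smoother at zero,
and divides by the mean *rectified* (unsmoothed) baseline activity. The
normalized output is scale-invariant to channel gain.

## Segmentation

Thresholds: 15°/s on angular velocity (central difference of the filtered
angle, flexion positive) and 5 % of the windowed peak COP speed. The rule
"until it peaked and fell below" is operationalized peak-first: locate the
phase's velocity extremum, then take the first threshold crossing after it,
which is robust to jitter-induced early dips. Crossings are linearly
interpolated between samples and reported as the nearest integer index,
exact ties rounding toward the phase interior. A 50 ms minimum
above-threshold run guards onsets against micro-phases (set
`min_duration=0` for the strict literal rule). The APA search window is 2 s
before flexion onset; COP *speed* (|velocity|) is used for the 5 %
criterion. Exactly one movement cycle per trial is assumed; a second cycle
raises an explicit error unless `allow_multiple_cycles` is set.

On unfiltered raised-cosine profiles every boundary matches its closed-form
crossing time to ≤2 samples. Through the 6 Hz zero-phase filter the
*velocity* crossings stay within ~2–3 samples, but the APA onset moves
~10–14 ms earlier: the filter smears the corner where the COP speed leaves
zero, an effect inherent to any 6 Hz smoother, not to the detector. Peak
features are insensitive to these shifts.

## Features

The maximum flexion angle is searched over flexion ∪ switch because the
angular peak can sit just inside the switch window under threshold-based
bounds. COP displacements are referenced to the mean COP over the 500 ms
preceding the APA onset. The flexion-phase COP maximum is read strictly
inside the detected flexion phase, which ends at the 15°/s down-crossing
slightly before the kinematic peak — a systematic ~1 % shortfall for
profiles whose COP peaks with the angle.

CCI is computed per sample with EMG_low/EMG_high the smaller/larger
envelope; 0 ≤ CCI ≤ 1 with equality at 1 iff the envelopes are equal and
nonzero. Samples where both envelopes are zero are defined as 0
(co-contraction of silent muscles is absent); `zero_policy="exclude"` drops
them instead.

Band powers use a complex Morlet wavelet of 7 cycles (σ_f = f/7; the
wavelet family is standard for this analysis, and 7 cycles is the common
time–frequency compromise) on a 1 Hz analysis grid per band, evaluated on a
window padded by 1 s of surrounding signal so edge effects fall outside the
scored interval. The per-frequency power is calibrated so a pure tone of
amplitude a at the analysis frequency contributes a²/2 (verified against
pywavelets' `cmor` response, |coef| = 0.5·a·√scale); band power is the mean
over grid frequencies and window time, floored at 10⁻¹² µV² before the
natural log. The α/β ratio divides the *logs* of the band powers, exactly
as defined for this analysis; because a ratio of logs is unit-sensitive,
powers are in µV² with planted task powers ≫ 1, and a |ln P_β| < 10⁻³
denominator raises an explicit undefined-ratio error rather than returning
an arbitrary number. The Fp entry averages the Fp1 and Fp2 *ratios*, after
all other computations. Windows shorter than two cycles of the band's lower
edge are rejected with the binding constraint named.

Trials aggregate to one vector per subject-condition by the feature-wise
mean of the (default three) trials; median is available. The underlying
study does not state its aggregation; the mean is the least surprising
reduction.

## Statistics

The forest uses 500 trees, Gini impurity and √p features per split —
conventional defaults, none stated by the underlying study. AUC comes from
out-of-bag class-probability votes by default; for paired tables
`validation="grouped"` scores subject-level cross-validation instead,
because OOB votes leak subject identity when the same subject appears in
both classes (the leakage can push OOB AUC far below 0.5 — see README).

The signed-rank test drops zero differences (counted and reported), uses an
exact null distribution for ≤25 nonzero pairs — a dynamic program over
doubled midranks, so ties are handled exactly — and the normal
approximation with continuity and tie correction beyond; at n = 35 pairs
the asymptotic path is the operative one. The effect size is r = Z/√N with
N the number of pairs and the sign taken from the median paired difference
(vision − no-vision, so a positive r means the vision value is larger); in
exact mode Z is recovered from the exact p. The 95 % CI is the
Hodges–Lehmann construction on the Walsh averages of the paired
differences, with the order statistic chosen by the normal approximation to
the signed-rank null. No multiple-testing correction is applied, matching
the analysis being reproduced; the report prints the number of tests.

## Validation problem sizes

The test suite plants and recovers: single noise-free trials for the
kinematic/COP chain (tolerances 1–2 %); closed-form crossing times for all
five boundaries (≤2 samples at 1 kHz); exact-test agreement with full sign
enumeration for n ≤ 10; forest sanity on 300-row tables (a separable
feature ranks first with OOB AUC > 0.95, 20 permuted-label replicates stay
in [0.35, 0.65]); and 20-cohort sweeps at n = 35 for the null
false-positive rate and the planted-effect power. The 20-run sweeps operate
on the generator's planted-parameter feature tables — the analytic limit of
the signal chain, whose agreement with full extraction is itself tested on
single trials and a small end-to-end cohort — which keeps the whole suite
at minutes scale.

## Known limitations

* The generator's condition effects are additive shifts; condition-specific
  variance changes (visible in some reported IQRs) are not modelled.
* The α/β ratio-of-logs is scale-dependent by definition; comparisons are
  only meaningful within the package's µV² convention.
* Real-data AUC values obtained under unstated validation schemes cannot be
  compared directly with either the OOB or the grouped figure here.
* ICA-based EEG artifact removal is out of scope; the artifact hook accepts
  any channel-set transform.
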