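"""Generate one synthetic trial and segment it into movement phases.

A standing trunk flexion-extension trial is planted with the raised-cosine
kinematic generator (peak angle 48.8 deg, peak flexion velocity 80 deg/s),
filtered, and segmented by the 15 deg/s angular-velocity rule plus the
5%-of-peak-COP-speed APA onset.  The printed boundaries are sample indices
at 1 kHz; the APA phase should start ~0.3 s before flexion onset, matching
the planted COP lead time.
"""

from posturekit import CopPlan, KinematicPlan, generate_trial, process_trial, segment

kin = KinematicPlan(peak_angle=48.8, peak_flex_velocity=80.0, switch_duration=0.5)
cop = CopPlan(apa_amplitude=7.0, flexion_displacement=47.4, apa_lead_time=0.3)
rec = generate_trial(kin, cop, seed=1)
print(f"trial: {rec.n_samples} samples at {rec.fs:.0f} Hz ({rec.duration:.1f} s)")

seg = segment(process_trial(rec))
for name, idx in seg.to_dict()["indices"].items():
    print(f"{name:>17s}: sample {idx:6d}  ({idx / seg.fs:7.3f} s)")
for phase in ("apa", "flexion", "switch", "extension"):
    print(f"{phase:>17s} duration: {seg.duration(phase):.3f} s")
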