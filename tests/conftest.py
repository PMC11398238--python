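import pytest

from posturekit.config import PipelineConfig
from posturekit.plans import CopPlan, EmgPlan, KinematicPlan, Timeline
from posturekit.synth import CohortConfig, generate_trial

FS = 1000.0


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_plans() -> tuple[KinematicPlan, CopPlan]:
    return (
        KinematicPlan(peak_angle=48.8, peak_flex_velocity=80.0, switch_duration=0.5),
        CopPlan(apa_amplitude=7.0, flexion_displacement=47.4, apa_lead_time=0.3),
    )


@pytest.fixture(scope="session")
def noise_free_trial(default_plans):
    """Deterministic trial with the vision-condition median kinematics planted."""
    kin, cop = default_plans
    return generate_trial(kin, cop, EmgPlan(noise_sd=0.0), seed=1)


@pytest.fixture(scope="session")
def timeline(default_plans) -> Timeline:
    kin, cop = default_plans
    return Timeline.from_plans(kin, cop)


@pytest.fixture(scope="session")
def tiny_cohort_config() -> CohortConfig:
    """Small cohort for end-to-end runs (full signal synthesis per trial)."""
    return CohortConfig(n_subjects=4, n_trials=2, seed=7)
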