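import numpy as np
import pytest

from actionselect.kinematics import DetectionConfig
from actionselect.synth import CohortConfig, SubjectParams
from actionselect.task_design import (
    Condition,
    CueStimulus,
    Direction,
    Shape,
    Size,
    TrialSpec,
    build_rule_map,
)


@pytest.fixture(scope="session")
def rule_map():
    return build_rule_map("standard")


@pytest.fixture
def pipeline_detection():
    """Detection settings used by the end-to-end analysis (10-Hz smoothing)."""
    return DetectionConfig(smoothing_cutoff_hz=10.0)


def make_subject_params(noise_sd=0.0, rt_mean=0.6, error_prob=0.0, **kw) -> SubjectParams:
    conds = [(c, d) for c in Condition for d in (1, 2, 3, 4)]
    defaults = dict(
        rt_mean_s={k: rt_mean for k in conds},
        error_prob={k: error_prob for k in conds},
        omission_prob=0.0,
        anticipation_prob=0.0,
        position_noise_sd_deg=noise_sd,
    )
    defaults.update(kw)
    return SubjectParams(**defaults)


def make_trial(direction=Direction.RIGHT, iti=3.0, cue_onset=0.0, condition=Condition.EXECUTE):
    return TrialSpec(
        trial_index=0,
        condition=condition,
        cue=CueStimulus(Shape.SQUARE, Size.LARGE),
        prescribed_direction=direction,
        cue_onset=cue_onset,
        iti=iti,
    )


@pytest.fixture
def noiseless_params():
    return make_subject_params(noise_sd=0.0)


@pytest.fixture
def tiny_cohort_config():
    """Four subjects, one block per condition per day: fast but full-shape."""
    return CohortConfig(
        n_subjects=4,
        master_seed=123,
        day1_blocks_per_condition=1,
        later_blocks_per_condition=1,
        include_familiarization=False,
    )
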