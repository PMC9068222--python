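"""Shared fixtures: reference parameter sets and small synthetic cohorts."""

import numpy as np
import pytest

from adaptcomp import LearnerParams
from adaptcomp.synth import CohortSpec, generate_cohort, make_schedule

#: Two-learner fit to the first savings exposure (reference condition of the
#: competition map); the second exposure raises b_i by 41.5% and b_e by 70.6%.
HAITH_DAY1 = dict(a_i=0.9829, b_i=0.0629, a_e=0.9278, b_e=0.0632)
HAITH_DAY2 = dict(a_i=0.9829, b_i=0.089, a_e=0.9278, b_e=0.1078)

#: Epoch-level implicit parameters of the limit-preparation-time condition.
LIMIT_PT_EPOCH = dict(a_i=0.943, b_i=0.35)


@pytest.fixture
def haith_params() -> LearnerParams:
    return LearnerParams(**HAITH_DAY1)


@pytest.fixture
def limit_pt_params() -> LearnerParams:
    return LearnerParams(**LIMIT_PT_EPOCH)


@pytest.fixture(scope="session")
def stepwise_competition_cohort():
    """Stepwise-rotation cohort generated from the competition model."""
    sched = make_schedule("stepwise", trials_per_epoch=4, n_targets=3)
    spec = CohortSpec(
        n_subjects=30,
        schedule=sched,
        params=LearnerParams(a_i=0.985, b_i=0.0895, a_e=0.95, b_e=0.15),
        model="competition",
        motor_noise_sd=3.0,
        seed=0,
        param_distributions={"b_e": (0.15, 0.08, (0.01, 0.6))},
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def stepwise_generalization_cohort():
    """Stepwise cohort from the SPE + aim-centred generalization rival."""
    from adaptcomp.rivals import GeneralizationCurve

    sched = make_schedule("stepwise", trials_per_epoch=4, n_targets=3)
    spec = CohortSpec(
        n_subjects=30,
        schedule=sched,
        params=LearnerParams(a_i=0.98, b_i=0.0125, a_e=0.95, b_e=0.25),
        model="independence",
        motor_noise_sd=3.0,
        seed=0,
        probe_generalization=GeneralizationCurve(),
        param_distributions={"b_e": (0.25, 0.1, (0.02, 0.7))},
    )
    return generate_cohort(spec)
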