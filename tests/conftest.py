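"""Shared fixtures: small hand-built and simulated cohorts."""

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from jointpsa.data import Cohort, LongitudinalObs, SubjectBaseline, TransformSpec
from jointpsa.simulate import SimConfig, generate_cohort


def make_subject(
    subject_id="S1",
    hormone=0,
    dose="le50",
    stage="1-2",
    gleason="2-5",
    age=70.0,
    event_time=2.0,
    event=0,
):
    return SubjectBaseline(
        subject_id=subject_id,
        hormone_therapy=hormone,
        dose_group=dose,
        stage_group=stage,
        gleason_group=gleason,
        age=age,
        event_time=event_time,
        event=event,
    )


def make_cohort(subject_specs, obs_specs, transform=TransformSpec()):
    """Build a cohort from (subject kwargs) and (sid, time, psa_raw) triples."""
    from jointpsa.data import transform_psa

    subjects = [make_subject(**s) for s in subject_specs]
    observations = [
        LongitudinalObs(
            subject_id=sid, time=t, psa_raw=raw, psa_star=transform_psa(raw, transform)
        )
        for sid, t, raw in obs_specs
    ]
    return Cohort(subjects=subjects, observations=observations, transform=transform)


@pytest.fixture
def two_subject_cohort():
    return make_cohort(
        [
            {"subject_id": "A", "event_time": 1.5, "event": 1},
            {
                "subject_id": "B",
                "hormone": 1,
                "dose": "ge70",
                "stage": "3-4",
                "gleason": "7",
                "age": 61.0,
                "event_time": 2.0,
                "event": 0,
            },
        ],
        [
            ("A", 0.0, 5.0),
            ("A", 0.5, 6.1),
            ("A", 1.0, 7.4),
            ("B", 0.0, 3.3),
            ("B", 0.5, 2.8),
            ("B", 1.0, 2.2),
        ],
    )


@pytest.fixture(scope="session")
def small_sim_cohort():
    """Simulated cohort, 40 subjects — shared read-only across tests."""
    return generate_cohort(SimConfig(n_subjects=40, seed=404))


@pytest.fixture(scope="session")
def medium_sim_cohort():
    """Simulated cohort, 120 subjects — shared read-only across tests."""
    return generate_cohort(SimConfig(n_subjects=120, seed=777))
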