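import numpy as np
import pytest

from ncdalgo.norms import DomainScores
from ncdalgo.records import (
    BAYER_ITEMS,
    BEHAVIOR_FLAGS,
    DEXQ_ITEMS,
    DOMAINS,
    ParticipantRecord,
    default_battery,
)
from ncdalgo.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def battery():
    return default_battery()


@pytest.fixture(scope="session")
def small_cohort(battery):
    """A 400-participant simulated cohort shared across read-only tests."""
    records, truth = simulate_cohort(SimConfig(n=400, seed=5), battery)
    return records, truth


def make_record(**overrides) -> ParticipantRecord:
    """A fully-observed record with benign defaults, informant present."""
    base = dict(
        participant_id="T0",
        sex="female",
        education_years=12,
        age_years=75,
        raw_scores={},
        mmse_w3=29,
        mmse_w4=29,
        macq_total=18,
        phq9_total=2,
        hrs_iadl_memory_problem=False,
        needs_care_help=False,
        informant_available=True,
        iqcode_mean=3.0,
        bayer_iadl_mean=2.0,
        bayer_item_difficulty={i: False for i in BAYER_ITEMS},
        dexq_freq={i: 0 for i in DEXQ_ITEMS},
        informant_behavior_flags={f: False for f in BEHAVIOR_FLAGS},
        informant_worsening=False,
        doctor_consult_cognition=False,
        history_psychosis=False,
        prior_path_diagnosis="none",
        onset_months_ago=12.0,
        delirium_signs=False,
        delirium_duration_months=None,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


def make_scores(domain_z=None, decline_z=None, test_z=None) -> DomainScores:
    """DomainScores with unspecified domains at z=0 (observed, unimpaired)."""
    dz = {d: 0.0 for d in DOMAINS}
    if domain_z:
        dz.update(domain_z)
    return DomainScores(
        domain_z=dz,
        test_z=dict(test_z or {}),
        decline_z=dict(decline_z or {}),
        n_tests_used={d: (1 if dz[d] is not None else 0) for d in DOMAINS},
    )


def random_record_and_scores(rng: np.random.Generator):
    """A random record/score pair exercising missing data and all clauses."""

    def tri():
        return rng.choice([True, False, None])

    def maybe(value, p=0.8):
        return value if rng.random() < p else None

    informant = rng.random() < 0.85
    rec = make_record(
        participant_id=f"R{rng.integers(1e6)}",
        sex=rng.choice(["male", "female"]),
        macq_total=maybe(int(rng.integers(7, 36))),
        phq9_total=maybe(int(rng.integers(0, 28))),
        mmse_w3=maybe(int(rng.integers(15, 31))),
        mmse_w4=maybe(int(rng.integers(15, 31))),
        hrs_iadl_memory_problem=tri(),
        needs_care_help=tri(),
        informant_available=informant,
        iqcode_mean=maybe(float(rng.uniform(1, 5))) if informant else None,
        bayer_iadl_mean=maybe(float(rng.uniform(1, 8))) if informant else None,
        bayer_item_difficulty={
            i: (tri() if informant else None) for i in BAYER_ITEMS
        },
        dexq_freq={
            i: (maybe(int(rng.integers(0, 5))) if informant else None)
            for i in DEXQ_ITEMS
        },
        informant_behavior_flags={
            f: (tri() if informant else None) for f in BEHAVIOR_FLAGS
        },
        informant_worsening=tri() if informant else None,
        doctor_consult_cognition=tri() if informant else None,
        history_psychosis=tri() if informant else None,
        onset_months_ago=maybe(float(rng.uniform(0, 60))) if informant else None,
        delirium_signs=tri() if informant else None,
        delirium_duration_months=(
            maybe(float(rng.uniform(0, 24)), 0.5) if informant else None
        ),
    )
    if not informant:
        rec.hrs_iadl_memory_problem = tri()
        rec.needs_care_help = tri()
    domain_z = {
        d: (float(rng.normal(-1.0, 1.2)) if rng.random() < 0.9 else None)
        for d in DOMAINS
    }
    battery = default_battery()
    test_z = {}
    for d, tests in battery.domain_map.items():
        for t in tests:
            if domain_z[d] is not None:
                test_z[t] = float(domain_z[d] + rng.normal(0, 0.3))
    decline_z = {
        t: (float(rng.normal(-0.5, 1.0)) if rng.random() < 0.8 else None)
        for t in battery.decline_tests
    }
    scores = DomainScores(
        domain_z=domain_z,
        test_z=test_z,
        decline_z=decline_z,
        n_tests_used={d: (1 if domain_z[d] is not None else 0) for d in DOMAINS},
    )
    return rec, scores
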