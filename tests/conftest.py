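import pytest

from mortsens import GeneratorConfig, PatientRecord, generate_cohort


def make_record(
    pid="p", index=0.0, arm="cohort", ehr=None, gold=None, last=None
) -> PatientRecord:
    if last is None:
        last = gold if gold is not None else max(index, 100.0)
    return PatientRecord(
        patient_id=pid,
        index_date=index,
        arm=arm,
        ehr_death_date=ehr,
        gold_death_date=gold,
        last_activity_date=last,
    )


@pytest.fixture
def toy_cohort():
    """Six patients covering the four presence patterns: A,A,B,C,C,D."""
    return [
        make_record("p0", ehr=100.0, gold=100.0),
        make_record("p1", ehr=210.0, gold=200.0, last=200.0),
        make_record("p2", ehr=150.0, gold=None, last=120.0),
        make_record("p3", ehr=None, gold=300.0, last=250.0),
        make_record("p4", ehr=None, gold=90.0, last=30.0),
        make_record("p5", ehr=None, gold=None, last=400.0),
    ]


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate synthetic cohort under the default study conditions."""
    return generate_cohort(GeneratorConfig(n_per_arm=2000, seed=20260927))


@pytest.fixture(scope="session")
def perfect_capture_cohort():
    """Cohort with 100% death capture and no false positives."""
    return generate_cohort(
        GeneratorConfig(
            n_per_arm=1500,
            target_sensitivity=1.0,
            false_positive_rate=0.0,
            seed=7,
        )
    )
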