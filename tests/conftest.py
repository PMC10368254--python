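import datetime as dt

import pytest

from ehrepi.cohort_builder import FollowUp
from ehrepi.registry_model import (
    Chronicity,
    ClinicalEvent,
    DiseaseDefinition,
    PatientRecord,
)


def d(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)


def make_patient(
    pid: str = "p1",
    reg: str = "2005-01-01",
    last: str = "2020-12-31",
    quality_start: str | None = None,
    transfer: str | None = None,
    death: str | None = None,
    acceptable: bool = True,
    duplicate: bool = False,
) -> PatientRecord:
    return PatientRecord(
        patient_id=pid,
        registration_date=d(reg),
        quality_start_date=d(quality_start) if quality_start else None,
        transfer_out_date=d(transfer) if transfer else None,
        death_date=d(death) if death else None,
        last_collection_date=d(last),
        acceptable_quality=acceptable,
        duplicate_excluded=duplicate,
    )


def make_events(pid: str, dates: list[str], code: str = "C1") -> list[ClinicalEvent]:
    return [
        ClinicalEvent(patient_id=pid, event_date=d(x), code=code) for x in dates
    ]


@pytest.fixture
def lifelong_disease() -> DiseaseDefinition:
    return DiseaseDefinition(
        name="mnd", chronicity=Chronicity.lifelong, codes=frozenset({"C1"})
    )


@pytest.fixture
def acute_disease() -> DiseaseDefinition:
    return DiseaseDefinition(
        name="lyme",
        chronicity=Chronicity.acute,
        expected_duration_days=28,
        codes=frozenset({"C1"}),
    )


def follow_up(pid: str = "p1", start: str = "2005-01-01", end: str = "2020-12-31") -> FollowUp:
    return FollowUp(pid, d(start), d(end))
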