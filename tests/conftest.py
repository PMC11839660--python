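import datetime as dt

import pytest

from vigilstat.reports import (
    DrugEntry,
    DrugRole,
    Occupation,
    Outcome,
    ReportRecord,
    ReportSet,
    Sex,
)


def make_report(
    case_id,
    reactions,
    *,
    version=1,
    drugs=(("rosuvastatin", DrugRole.PRIMARY_SUSPECT), ("fenofibrate", DrugRole.PRIMARY_SUSPECT)),
    sex=Sex.UNKNOWN,
    age=None,
    occupation=Occupation.UNKNOWN,
    outcomes=(),
    date=None,
):
    return ReportRecord(
        case_id=case_id,
        case_version=version,
        drugs=tuple(DrugEntry(n, r) for n, r in drugs),
        reactions=frozenset(reactions),
        sex=sex,
        age_years=age,
        occupation=occupation,
        outcomes=frozenset(outcomes),
        receipt_date=dt.date.fromisoformat(date) if date else None,
    )


@pytest.fixture
def tiny_cohort():
    """Three exposed reports + two background reports with known counts."""
    exposed = ReportSet(
        [
            make_report("E1", {"Nausea", "Myalgia"}),
            make_report("E2", {"Nausea"}),
            make_report("E3", {"Headache"}),
        ]
    )
    background = ReportSet(
        [
            make_report("B1", {"Rash"}, drugs=(("aspirin", DrugRole.PRIMARY_SUSPECT),)),
            make_report("B2", {"Nausea", "Rash"}, drugs=(("aspirin", DrugRole.PRIMARY_SUSPECT),)),
        ]
    )
    return exposed, background
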