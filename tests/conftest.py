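from datetime import date

import pytest

from estihiv import (
    ArtStatus,
    ClinicPopulation,
    Gender,
    PatientRecord,
    TransmissionGroup,
)

WINDOW_2017 = (date(2017, 1, 1), date(2017, 12, 31))


def make_record(patient_id="p1", visit=date(2017, 6, 15), dob=date(1980, 1, 1),
                vl=None, on_art="yes", **kwargs) -> PatientRecord:
    """A valid adult record with overridable fields."""
    return PatientRecord(
        patient_id=patient_id,
        last_visit_date=visit,
        date_of_birth=dob,
        gender=kwargs.pop("gender", Gender.MALE),
        transmission_group=kwargs.pop("transmission_group", TransmissionGroup.MSM),
        last_vl=vl,
        last_vl_date=visit if vl is not None else None,
        on_art=ArtStatus(on_art),
        **kwargs,
    )


def make_population(records, window=WINDOW_2017, **kwargs) -> ClinicPopulation:
    return ClinicPopulation(records=tuple(records),
                            window_start=window[0], window_end=window[1],
                            **kwargs)


def csv_row(patient_id="p1", visit="2017-06-15", dob="1980-01-01", **overrides):
    """One input CSV row (as a dict) with sensible defaults."""
    row = {
        "patient_id": patient_id,
        "date_of_birth": dob,
        "gender": "male",
        "country_of_origin": "XX",
        "transmission_group": "MSM",
        "last_cd4": "550",
        "last_cd4_date": visit,
        "last_vl": "40",
        "last_vl_date": visit,
        "on_art": "yes",
        "art_status_date": visit,
        "hiv_diagnosis_date": "2010-01-01",
        "first_visit_date": "2010-02-01",
        "last_visit_date": visit,
        "death_date": "",
    }
    row.update(overrides)
    return row


@pytest.fixture
def ten_person_pop():
    """10 eligible adults: 9 on ART, 7 suppressed, 1 with missing VL."""
    records = []
    for i in range(10):
        records.append(make_record(
            patient_id=f"p{i:02d}",
            vl=None if i == 9 else (50 if i < 7 else 5000),
            on_art="no" if i == 8 else "yes",
        ))
    return make_population(records)
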