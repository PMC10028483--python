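import numpy as np
import pandas as pd
import pytest

import pnukit as pk


@pytest.fixture(scope="session")
def code_lists():
    return pk.default_code_lists()


@pytest.fixture(scope="session")
def charlson_map():
    return pk.load_charlson_map()


_PERSON_DEFAULTS = {
    "birth_year": 1930,  # age 42 at a day-1000 (1972) index
    "sex": "male",
    "race_ethnicity": "White",
    "region": "South",
    "education": "high school diploma",
    "outpatient_visits_per_year": 5.0,
}


def make_bundle(persons, enrollment, diagnoses=(), fills=(), procedures=()):
    """Assemble a ClaimsBundle from compact row tuples.

    persons: [{person_id, ...overrides}]; enrollment: [(pid, start, end)];
    diagnoses: [(pid, date, system, code)]; fills: [(pid, date, class,
    supply)]; procedures: [(pid, date, cpt)].
    """
    prs = pd.DataFrame([{**_PERSON_DEFAULTS, **p} for p in persons])
    enr = pd.DataFrame(enrollment, columns=["person_id", "spell_start", "spell_end"])
    dx = pd.DataFrame(
        list(diagnoses), columns=["person_id", "service_date", "code_system", "code"]
    )
    fl = pd.DataFrame(
        list(fills), columns=["person_id", "fill_date", "drug_class", "days_supply"]
    )
    pr = pd.DataFrame(list(procedures), columns=["person_id", "service_date", "cpt_code"])
    return pk.ClaimsBundle(
        persons=prs, enrollment=enr, diagnoses=dx, fills=fl, procedures=pr
    )


def eligible_person(pid, index_day=1000, group="metformin", n_fills=6, birth_year=1930):
    """Rows for one fully eligible initiator: enrollment, qualifying T2D
    codes, and monthly fills starting at index_day."""
    persons = {"person_id": pid, "birth_year": birth_year}
    enrollment = (pid, index_day - 500, index_day + 3000)
    diagnoses = [
        (pid, index_day - 100, "ICD9", "250.00"),
        (pid, index_day - 80, "ICD9", "250.00"),
    ]
    fills = [(pid, index_day + 30 * k, group, 30) for k in range(n_fills)]
    return persons, enrollment, diagnoses, fills


def bundle_of(people):
    """Build a bundle from a list of eligible_person(...) outputs plus extras."""
    persons, enrollment, diagnoses, fills = [], [], [], []
    for p, e, d, f in people:
        persons.append(p)
        enrollment.append(e)
        diagnoses.extend(d)
        fills.extend(f)
    return make_bundle(persons, enrollment, diagnoses, fills)


def make_cohort_records(rows):
    """Cohort-record frame for matching tests.

    rows: dicts with person_id, group; defaults fill the rest.
    """
    defaults = {
        "index_date": 1000,
        "prior_metformin": False,
        "first_met_date": np.nan,
        "followup_start": 1090,
        "followup_end": 2000,
        "followup_end_jr": 2000,
        "event_oa": False,
        "event_jr": False,
        "censor_reason": "study_end",
        "age": 60,
        "sex": "male",
        "race_ethnicity": "White",
        "region": "South",
        "education": "high school diploma",
        "charlson": 0,
        "visits": 5.0,
        "treatment_duration_months": 12.0,
        "followup_months": 9.0,
    }
    recs = [{**defaults, **r} for r in rows]
    return pd.DataFrame(recs)
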