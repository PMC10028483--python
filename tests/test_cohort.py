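"""Phenotyping, episode construction, eligibility, and censoring rules."""

import numpy as np
import pandas as pd
import pytest

import pnukit as pk

from conftest import bundle_of, eligible_person, make_bundle
from oracles import brute_two_code_date, day_scan_episodes


# ------------------------------------------------------------- T2D phenotype
@pytest.mark.parametrize(
    "days, qualifies",
    [
        ([0, 14], True),   # boundary inclusive
        ([0, 13], False),
        ([0], False),
        ([5, 10, 40], True),
        ([], False),
    ],
)
def test_t2d_two_code_separation(code_lists, days, qualifies):
    dx = pd.DataFrame(
        [(1, d, "ICD9", "250.00") for d in days],
        columns=["person_id", "service_date", "code_system", "code"],
    )
    out = pk.identify_t2d(dx, code_lists)
    assert (len(out) == 1) == qualifies
    if qualifies:
        assert out["first_t2d"].iloc[0] == min(days)


def test_t2d_ignores_other_code_families(code_lists):
    dx = pd.DataFrame(
        [(1, 0, "ICD10", "M17.9"), (1, 30, "ICD10", "M17.9")],
        columns=["person_id", "service_date", "code_system", "code"],
    )
    assert len(pk.identify_t2d(dx, code_lists)) == 0


# ------------------------------------------------------------------ episodes
def _fills(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "fill_date", "drug_class", "days_supply"]
    )


def test_contiguous_fills_one_episode():
    ep = pk.build_treatment_episodes(_fills([(1, 0, "metformin", 30), (1, 30, "metformin", 30)]))
    assert len(ep) == 1
    assert ep.iloc[0]["episode_start"] == 0
    assert ep.iloc[0]["episode_end"] == 60
    assert ep.iloc[0]["total_covered_days"] == 60


def test_ninety_day_gap_splits_episode():
    # uncovered run [30, 120) is exactly 90 days -> split (boundary inclusive)
    ep = pk.build_treatment_episodes(_fills([(1, 0, "metformin", 30), (1, 120, "metformin", 30)]))
    assert len(ep) == 2
    assert ep.iloc[0]["episode_end"] == 30  # stop = supply exhaustion


def test_eighty_nine_day_gap_does_not_split():
    ep = pk.build_treatment_episodes(_fills([(1, 0, "metformin", 30), (1, 119, "metformin", 30)]))
    assert len(ep) == 1
    assert ep.iloc[0]["total_covered_days"] == 60


def test_nonpositive_supply_rejected():
    with pytest.raises(pk.ValidationError):
        pk.build_treatment_episodes(_fills([(1, 0, "metformin", 0)]))


def test_episodes_match_day_scan_oracle():
    rng = np.random.default_rng(42)
    rows = []
    for pid in range(40):
        n = rng.integers(1, 8)
        dates = np.sort(rng.integers(0, 500, size=n))
        for d in dates:
            rows.append((pid, int(d), "metformin", int(rng.integers(7, 60))))
    got = pk.build_treatment_episodes(_fills(rows))
    expected = day_scan_episodes(
        [(p, c, d, s) for p, d, c, s in rows], gap_days=90
    )
    got_tuples = sorted(
        (int(r.person_id), r.drug_class, int(r.episode_start),
         int(r.episode_end), int(r.total_covered_days))
        for r in got.itertuples()
    )
    assert got_tuples == expected


# --------------------------------------------------------------- eligibility
def _cohort(bundle, study_end=20000, **kw):
    return pk.build_cohort(bundle, study_end, **kw)


def test_age_forty_boundary():
    # index day 1000 is in 1972; birth 1933 -> 39, excluded; 1932 -> 40, kept
    young = eligible_person(1, birth_year=1933)
    old = eligible_person(2, birth_year=1932)
    rec, att = _cohort(bundle_of([young, old]))
    assert set(rec["person_id"]) == {2}
    assert att["excluded_age_under_40"] == 1


def test_oa_code_on_day_89_excludes_but_day_90_does_not():
    p1 = eligible_person(1)
    p2 = eligible_person(2)
    bundle = bundle_of([p1, p2])
    extra = pd.DataFrame(
        [
            (1, 1089, "ICD9", "715.90"),  # day 89 after index: excluded
            (1, 1120, "ICD9", "715.90"),
            (2, 1090, "ICD9", "715.90"),  # day 90: outcome, not exclusion
            (2, 1120, "ICD9", "715.90"),
        ],
        columns=["person_id", "service_date", "code_system", "code"],
    )
    bundle.diagnoses = pd.concat([bundle.diagnoses, extra], ignore_index=True)
    rec, att = _cohort(bundle)
    assert att["excluded_prior_oa"] == 1
    assert set(rec["person_id"]) == {2}
    assert bool(rec.iloc[0]["event_oa"])
    assert rec.iloc[0]["followup_end"] == 1090


def test_same_day_dual_start_excluded():
    p, e, d, f = eligible_person(1)
    f = f + [(1, 1000, "sulfonylurea", 30)]
    rec, att = _cohort(bundle_of([(p, e, d, f)]))
    assert len(rec) == 0
    assert att["excluded_same_day_dual_start"] == 2  # both candidate records


def test_type_1_diabetes_excluded():
    p, e, d, f = eligible_person(1)
    d = d + [(1, 600, "ICD10", "E10.9")]
    rec, att = _cohort(bundle_of([(p, e, d, f)]))
    assert len(rec) == 0 and att["excluded_type_1_diabetes"] == 1


def test_under_90_covered_days_excluded():
    short = eligible_person(1, n_fills=2)  # 60 covered days
    rec, att = _cohort(bundle_of([short]))
    assert len(rec) == 0 and att["excluded_under_90_treated_days"] == 1


def test_group_asymmetry_su_then_met():
    """Sulfonylurea-then-metformin yields only a sulfonylurea record,
    censored at the switch; metformin-then-sulfonylurea yields both."""
    p1, e1, d1, f1 = eligible_person(1, group="sulfonylurea")
    f1 = f1 + [(1, 1200, "metformin", 30) for _ in range(4)]
    p2, e2, d2, f2 = eligible_person(2, group="metformin")
    f2 = f2 + [(2, 1200, "sulfonylurea", 30), (2, 1230, "sulfonylurea", 30),
               (2, 1260, "sulfonylurea", 30)]
    rec, _ = _cohort(bundle_of([(p1, e1, d1, f1), (p2, e2, d2, f2)]))
    by = rec.groupby("person_id")["group"].apply(set)
    assert by[1] == {"sulfonylurea"}
    assert by[2] == {"metformin", "sulfonylurea"}
    r1 = rec[(rec["person_id"] == 1)].iloc[0]
    assert r1["censor_reason"] == "switch" and r1["followup_end"] == 1200
    su2 = rec[(rec["person_id"] == 2) & (rec["group"] == "sulfonylurea")].iloc[0]
    assert bool(su2["prior_metformin"])


def test_overlapping_enrollment_spells_rejected():
    p, e, d, f = eligible_person(1)
    bundle = bundle_of([(p, e, d, f)])
    dup = pd.DataFrame(
        [(1, e[1] + 10, e[2] + 10)], columns=["person_id", "spell_start", "spell_end"]
    )
    bundle.enrollment = pd.concat([bundle.enrollment, dup], ignore_index=True)
    with pytest.raises(pk.ValidationError, match="overlap"):
        _cohort(bundle)


# ----------------------------------------------------------------- follow-up
def test_oa_event_and_person_time_from_stated_rules():
    """OA pair at days 200/220 post-index with treatment maintained:
    event at day 200, at-risk time 110 days (200 - 90)."""
    p, e, d, f = eligible_person(1, n_fills=12)  # covered through day 360
    d = d + [(1, 1200, "ICD9", "715.90"), (1, 1220, "ICD9", "715.90")]
    rec, _ = _cohort(bundle_of([(p, e, d, f)]))
    r = rec.iloc[0]
    assert bool(r["event_oa"]) and r["censor_reason"] == "oa"
    assert r["followup_end"] - r["followup_start"] == 110


def test_disenrollment_before_oa_censors():
    p = {"person_id": 1}
    e = (1, 100, 1100)  # disenrolled 100 days after the day-1000 index
    d = [
        (1, 550, "ICD9", "250.00"),
        (1, 570, "ICD9", "250.00"),
        (1, 1150, "ICD9", "715.90"),  # OA pair after disenrollment
        (1, 1170, "ICD9", "715.90"),
    ]
    f = [(1, 1000 + 30 * k, "metformin", 30) for k in range(4)]
    rec, _ = _cohort(make_bundle([p], [e], d, f))
    r = rec.iloc[0]
    assert not bool(r["event_oa"])
    assert r["censor_reason"] == "disenrolled"
    assert r["followup_end"] == 1100


def test_followup_equals_duration_minus_three_months_on_stop():
    p, e, d, f = eligible_person(1, n_fills=6)  # coverage [1000, 1180)
    rec, _ = _cohort(bundle_of([(p, e, d, f)]))
    r = rec.iloc[0]
    assert r["censor_reason"] == "treatment_stop"
    assert r["followup_end"] == 1180
    assert r["treatment_duration_months"] - r["followup_months"] == pytest.approx(3.0)


def test_other_antidiabetic_censors():
    p, e, d, f = eligible_person(1, n_fills=12)
    f = f + [(1, 1150, "other_antidiabetic", 30)]
    rec, _ = _cohort(bundle_of([(p, e, d, f)]))
    r = rec.iloc[0]
    assert r["censor_reason"] == "other_diabetes_drug" and r["followup_end"] == 1150


def test_oa_diagnosis_does_not_censor_joint_replacement_endpoint():
    p, e, d, f = eligible_person(1, n_fills=12)
    d = d + [(1, 1200, "ICD9", "715.90"), (1, 1220, "ICD9", "715.90")]
    pr = [(1, 1300, "27447")]
    rec, _ = _cohort(
        make_bundle([p], [e], d, f, pr)
    )
    r = rec.iloc[0]
    assert bool(r["event_oa"]) and r["followup_end"] == 1200
    assert bool(r["event_jr"]) and r["followup_end_jr"] == 1300


# ------------------------------------------------- generated-bundle properties
def test_generated_cohort_invariants(code_lists):
    cfg = pk.SimConfig(n_persons=200, seed=21, baseline_oa_rate=0.1)
    bundle = pk.generate_population(cfg)
    rec, _ = pk.build_cohort(bundle, cfg.study_end)
    assert len(rec) > 50
    # immortal-time guard: no person-time before index + 90
    assert ((rec["followup_start"] - rec["index_date"]) == 90).all()
    assert (rec["followup_end"] >= rec["followup_start"]).all()
    # every OA event satisfies the two-code phenotype (brute-force oracle)
    oa = bundle.diagnoses[bundle.diagnoses["code"].isin(["715.90", "M17.9"])]
    oa_by_person = oa.groupby("person_id")["service_date"].apply(list)
    for r in rec[rec["event_oa"]].itertuples():
        dates = [t for t in oa_by_person[r.person_id] if t >= r.followup_start]
        assert brute_two_code_date(dates, 14) == r.followup_end
    # group asymmetry: metformin records never follow a sulfonylurea start
    first = bundle.fills.groupby(["person_id", "drug_class"])["fill_date"].min().unstack()
    met_rec = rec[rec["group"] == "metformin"]
    if "sulfonylurea" in first.columns:
        su_first = met_rec["person_id"].map(first["sulfonylurea"])
        met_first = met_rec["person_id"].map(first["metformin"])
        assert not (su_first < met_first).any()


def test_sensitivity_cohort_censors_only_disenrollment_and_study_end():
    cfg = pk.SimConfig(n_persons=400, seed=8)
    bundle = pk.generate_population(cfg)
    rec, att = pk.build_sensitivity_cohort(bundle, cfg.study_end)
    assert len(rec) > 20
    assert set(rec["censor_reason"]).issubset(
        {"oa", "joint_replacement", "disenrolled", "study_end"}
    )
    assert att["excluded_ever_other_antidiabetic"] > 0
    # only-ever-one-drug restriction
    classes = bundle.fills.groupby("person_id")["drug_class"].apply(set)
    assert rec["person_id"].map(classes).apply(len).eq(1).all()
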