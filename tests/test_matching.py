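"""Exposure sets, conditional-logistic PS, greedy and caliper matching, SMDs."""

import numpy as np
import pandas as pd
import pytest

import pnukit as pk
from pnukit.matching import _ps_design

from conftest import make_cohort_records
from oracles import (
    caliper_match_oracle,
    condlogit_loglik,
    greedy_match_oracle,
)


# ------------------------------------------------------------- exposure sets
def test_window_rule_includes_candidate_within_15_days():
    rec = make_cohort_records(
        [
            # su anchor: metformin started 100 days before sulfonylurea
            {"person_id": 1, "group": "sulfonylurea", "index_date": 1100,
             "prior_metformin": True, "first_met_date": 1000},
            # candidate at risk through offset 110 (index 1000, end 1110)
            {"person_id": 2, "group": "metformin", "index_date": 1000,
             "followup_end": 1110},
            # candidate whose outcome occurred at offset 80 < 100 - 15
            {"person_id": 3, "group": "metformin", "index_date": 1000,
             "followup_end": 1080, "event_oa": True},
        ]
    )
    sets = pk.build_exposure_sets(rec, window_days=15)
    assert len(sets) == 1
    assert sets.su["delta_t"].iloc[0] == 100
    cand = sets.met.iloc[sets.candidates(0)]["person_id"].tolist()
    assert cand == [2]


def test_no_prior_metformin_anchor_has_delta_zero():
    rec = make_cohort_records(
        [
            {"person_id": 1, "group": "sulfonylurea"},
            {"person_id": 2, "group": "metformin"},
            {"person_id": 3, "group": "metformin"},
        ]
    )
    sets = pk.build_exposure_sets(rec)
    assert sets.su["delta_t"].iloc[0] == 0
    assert len(sets.candidates(0)) == 2  # all at-risk initiators qualify


def test_anchor_person_never_own_candidate():
    rec = make_cohort_records(
        [
            {"person_id": 1, "group": "sulfonylurea", "index_date": 1100,
             "prior_metformin": True, "first_met_date": 1000},
            {"person_id": 1, "group": "metformin", "index_date": 1000,
             "followup_end": 1200},
            {"person_id": 2, "group": "metformin", "index_date": 1000,
             "followup_end": 1200},
        ]
    )
    sets = pk.build_exposure_sets(rec)
    assert sets.met.iloc[sets.candidates(0)]["person_id"].tolist() == [2]


# --------------------------------------------------- conditional-logistic PS
def _two_group_sets(charlson_pairs):
    """Sets of size 2 where the case/control differ only in Charlson score."""
    rows = []
    pid = 0
    for su_val, met_val in charlson_pairs:
        pid += 1
        rows.append({"person_id": pid, "group": "sulfonylurea", "charlson": su_val,
                     "index_date": 1000 + pid})
        pid += 1
        rows.append({"person_id": pid, "group": "metformin", "charlson": met_val})
    return pk.build_exposure_sets(make_cohort_records(rows))


def test_no_information_case_gives_zero_coefficients():
    sets = _two_group_sets([(1, 1), (2, 2)])
    ps = pk.fit_time_conditional_ps(sets, max_controls_per_set=None)
    assert np.allclose(ps.beta.to_numpy(), 0.0)
    assert np.allclose(ps.su_scores, ps.su_scores[0])


def test_coefficient_matches_grid_search_oracle():
    # one binary covariate; likelihood maximiser found by brute-force grid
    sets = _two_group_sets([(1, 0), (1, 0), (0, 1), (1, 0)])
    ps = pk.fit_time_conditional_ps(sets, max_controls_per_set=None)
    x = ps.beta.index.get_loc("charlson")
    strata = []
    for s in range(len(sets)):
        su_x = _ps_design(sets.su).to_numpy()[s]
        met_x = _ps_design(sets.met, list(_ps_design(sets.su).columns)).to_numpy()
        cands = met_x[sets.candidates(s)]
        strata.append((su_x, [su_x] + list(cands)))
    grid = np.linspace(-5, 5, 20001)
    lls = []
    for b in grid:
        beta = np.zeros(len(ps.beta))
        beta[x] = b
        lls.append(condlogit_loglik(beta, strata))
    assert abs(ps.beta["charlson"] - grid[int(np.argmax(lls))]) < 1e-3


def test_duplicated_strata_leave_coefficients_unchanged():
    """Replicating every stratum scales the partial likelihood but cannot
    move its maximiser."""
    from pnukit.matching import _softmax_fit

    rng = np.random.default_rng(3)
    X = rng.normal(size=(12, 2))
    bounds = np.array([0, 4, 8])
    case_pos = np.array([0, 4, 8])
    b1, _, conv1 = _softmax_fit(X, case_pos, bounds, 0.0)
    X2 = np.vstack([X, X])
    b2, _, conv2 = _softmax_fit(X2, np.r_[case_pos, case_pos + 12],
                                np.r_[bounds, bounds + 12], 0.0)
    assert conv1 and conv2
    assert np.allclose(b1, b2, atol=1e-6)


def test_agrees_with_statsmodels_conditional_logit():
    from statsmodels.discrete.conditional_models import ConditionalLogit

    rng = np.random.default_rng(0)
    rows = []
    pid = 0
    for s in range(30):
        pid += 1
        rows.append({"person_id": pid, "group": "sulfonylurea",
                     "charlson": int(rng.integers(0, 4)),
                     "age": int(rng.integers(45, 80)), "index_date": 1000 + s})
        for _ in range(3):
            pid += 1
            rows.append({"person_id": pid, "group": "metformin",
                         "charlson": int(rng.integers(0, 4)),
                         "age": int(rng.integers(45, 80))})
    sets = pk.build_exposure_sets(make_cohort_records(rows))
    ps = pk.fit_time_conditional_ps(sets, max_controls_per_set=None)

    y, X, groups = [], [], []
    for s in range(len(sets)):
        su_row = sets.su.iloc[s]
        y.append(1); X.append([su_row["age"], su_row["charlson"]]); groups.append(s)
        for c in sets.candidates(s):
            met_row = sets.met.iloc[c]
            y.append(0); X.append([met_row["age"], met_row["charlson"]]); groups.append(s)
    sm_fit = ConditionalLogit(np.array(y), np.array(X), groups=np.array(groups)).fit(disp=0)
    ours = np.array([ps.beta["age"], ps.beta["charlson"]])
    assert np.allclose(ours, sm_fit.params, atol=1e-3)
    # and our solution attains at least statsmodels' partial likelihood
    strata = []
    i = 0
    arrX = np.array(X)
    for s in range(30):
        members = arrX[np.array(groups) == s]
        strata.append((members[0], list(members)))
    assert condlogit_loglik(ours, strata) >= condlogit_loglik(np.asarray(sm_fit.params), strata) - 1e-8


# -------------------------------------------------------------------- greedy
def test_single_candidate_matched_without_caliper():
    rec = make_cohort_records(
        [
            {"person_id": 1, "group": "sulfonylurea", "charlson": 10},
            {"person_id": 2, "group": "metformin", "charlson": 0},
        ]
    )
    sets = pk.build_exposure_sets(rec)
    ps = pk.fit_time_conditional_ps(sets, max_controls_per_set=None)
    matched = pk.greedy_match(sets, ps)
    assert len(matched) == 1  # matched despite any score distance


def test_chronologically_earlier_set_wins_shared_candidate():
    rec = make_cohort_records(
        [
            {"person_id": 1, "group": "sulfonylurea", "index_date": 1000, "charlson": 1},
            {"person_id": 2, "group": "sulfonylurea", "index_date": 1005, "charlson": 1},
            {"person_id": 3, "group": "metformin", "charlson": 1},  # best for both
            {"person_id": 4, "group": "metformin", "charlson": 0},
        ]
    )
    sets = pk.build_exposure_sets(rec)
    ps = pk.fit_time_conditional_ps(sets, max_controls_per_set=None)
    matched = pk.greedy_match(sets, ps)
    got = {
        int(matched.su.iloc[r.su_pos]["person_id"]): int(
            matched.met.iloc[r.met_pos]["person_id"]
        )
        for r in matched.pairs.itertuples()
    }
    assert got == {1: 3, 2: 4}


@pytest.mark.parametrize("seed", range(6))
def test_greedy_identical_to_stepwise_oracle(seed):
    """<= 8-record random instances match a literal reference implementation."""
    rng = np.random.default_rng(seed)
    n_su, n_met = rng.integers(1, 4), rng.integers(1, 5)
    rows = []
    pid = 0
    for i in range(n_su):
        pid += 1
        rows.append({"person_id": pid, "group": "sulfonylurea",
                     "index_date": 1000 + int(rng.integers(0, 50)),
                     "charlson": int(rng.integers(0, 5)),
                     "age": int(rng.integers(45, 80))})
    for i in range(n_met):
        pid += 1
        rows.append({"person_id": pid, "group": "metformin",
                     "index_date": 1000 + int(rng.integers(0, 50)),
                     "followup_end": 1000 + int(rng.integers(100, 1000)),
                     "charlson": int(rng.integers(0, 5)),
                     "age": int(rng.integers(45, 80))})
    sets = pk.build_exposure_sets(make_cohort_records(rows))
    ps = pk.fit_time_conditional_ps(sets, max_controls_per_set=None)
    matched = pk.greedy_match(sets, ps)

    oracle_sets = [(s, list(sets.candidates(s))) for s in range(len(sets))]
    met_dates = sets.met["index_date"].to_numpy()
    met_pids = sets.met["person_id"].to_numpy()
    expected = greedy_match_oracle(
        oracle_sets, ps.su_scores, ps.met_scores, met_dates, met_pids
    )
    got = [(int(r.su_pos), int(r.met_pos)) for r in matched.pairs.itertuples()]
    assert got == [(s, c) for s, c in expected]


# ------------------------------------------------------------------- caliper
def _arm(group, n, seed, charlson_shift=0):
    rng = np.random.default_rng(seed)
    return [
        {"person_id": seed * 1000 + i, "group": group,
         "index_date": 1000 + int(rng.integers(0, 100)),
         "age": int(rng.integers(45, 80)),
         "charlson": int(rng.integers(0, 4)) + charlson_shift,
         "treatment_duration_months": float(rng.integers(3, 24))}
        for i in range(n)
    ]


def test_caliper_exchangeable_arms_match_fully_and_balance():
    rec = make_cohort_records(_arm("metformin", 100, 1) + _arm("sulfonylurea", 100, 2))
    matched = pk.caliper_match(
        rec[rec["group"] == "metformin"], rec[rec["group"] == "sulfonylurea"]
    )
    # greedy-without-replacement loses a few tail records to the caliper
    assert len(matched) >= 80
    bal = pk.balance_table(matched.records(), covariates=("age", "charlson"))
    assert (bal["smd"] < 0.1).all()


def test_caliper_rejects_extreme_record():
    rows = _arm("metformin", 40, 3) + _arm("sulfonylurea", 39, 4)
    rows.append({"person_id": 99999, "group": "sulfonylurea", "age": 60,
                 "charlson": 40, "treatment_duration_months": 12.0,
                 "index_date": 1100})
    rec = make_cohort_records(rows)
    matched = pk.caliper_match(
        rec[rec["group"] == "metformin"], rec[rec["group"] == "sulfonylurea"]
    )
    assert matched.n_unmatched >= 1
    su_matched = matched.su.iloc[matched.pairs["su_pos"]]["person_id"]
    assert 99999 not in set(su_matched)


def test_caliper_identical_to_oracle():
    rec = make_cohort_records(_arm("metformin", 12, 5) + _arm("sulfonylurea", 8, 6))
    met = rec[rec["group"] == "metformin"]
    su = rec[rec["group"] == "sulfonylurea"]
    matched = pk.caliper_match(met, su)
    # recompute the logit scores on the same sorted frames the
    # implementation uses, then drive the literal step-by-step oracle
    ms, ss = matched.met, matched.su
    met_logit, su_logit = _logits(ms, ss)
    expected = caliper_match_oracle(
        su_logit,
        met_logit,
        _caliper_width(ms, ss),
        ms["index_date"].to_numpy(),
        ms["person_id"].to_numpy(),
    )
    got = sorted((int(r.su_pos), int(r.met_pos)) for r in matched.pairs.itertuples())
    assert got == sorted(expected)


def _logits(met, su):
    import statsmodels.api as sm

    pooled = pd.concat([met, su], ignore_index=True)
    X = _ps_design(pooled)
    X = X.loc[:, X.std() > 1e-12]
    y = np.r_[np.zeros(len(met)), np.ones(len(su))]
    fit = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0, maxiter=200)
    logit = sm.add_constant(X, has_constant="add").to_numpy() @ np.asarray(fit.params)
    return logit[: len(met)], logit[len(met):]


def _caliper_width(met, su, caliper_sd=0.2):
    ml, sl = _logits(met, su)
    return caliper_sd * float(np.std(np.r_[ml, sl], ddof=1))


def test_degenerate_caliper_raises():
    # identical covariates in every record -> zero logit SD
    const = make_cohort_records(
        [{"person_id": i, "group": g} for i, g in
         enumerate(["metformin"] * 5 + ["sulfonylurea"] * 5)]
    )
    with pytest.raises(pk.ValidationError, match="caliper"):
        pk.caliper_match(
            const[const["group"] == "metformin"],
            const[const["group"] == "sulfonylurea"],
        )


# ------------------------------------------------------------------- balance
def test_identical_groups_have_zero_smd():
    rows = _arm("metformin", 30, 8)
    mirror = [dict(r, group="sulfonylurea", person_id=r["person_id"] + 10000) for r in rows]
    bal = pk.balance_table(make_cohort_records(rows + mirror))
    assert (bal["smd"] == 0).all()


def test_age_smd_from_printed_summary_statistics():
    # means 62.0 vs 62.1, SDs 11.1 vs 11.9 on rounded inputs
    smd = pk.smd_continuous(62.0, 11.1, 62.1, 11.9)
    assert abs(abs(smd) - 0.013) <= 0.005


def test_two_level_categorical_reduces_to_binary_formula():
    rows = []
    for i in range(40):
        rows.append({"person_id": i, "group": "metformin",
                     "sex": "male" if i % 4 else "female"})
    for i in range(40, 80):
        rows.append({"person_id": i, "group": "sulfonylurea",
                     "sex": "male" if i % 2 else "female"})
    rec = make_cohort_records(rows)
    bal = pk.balance_table(rec, covariates=("sex",)).set_index("covariate")
    p1 = (rec[rec["group"] == "metformin"]["sex"] == "female").mean()
    p2 = (rec[rec["group"] == "sulfonylurea"]["sex"] == "female").mean()
    binary = abs(p1 - p2) / np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2)
    assert bal.loc["sex", "smd"] == pytest.approx(binary, abs=1e-12)


def test_matching_reduces_injected_confounding():
    """Channeling by age creates imbalance that PS matching removes."""
    cfg = pk.SimConfig(
        n_persons=4000, seed=17, p_first_su=0.35,
        confounding_strength={"age": 0.06, "charlson": 0.25},
    )
    bundle = pk.inject_confounding(pk.generate_population(cfg), cfg)
    rec, _ = pk.build_cohort(bundle, cfg.study_end)
    covs = ("age", "charlson")
    pre = pk.balance_table(rec, covariates=covs)["smd"].max()
    sets = pk.build_exposure_sets(rec)
    ps = pk.fit_time_conditional_ps(sets, seed=1)
    matched = pk.greedy_match(sets, ps)
    post = pk.balance_table(matched.records(), covariates=covs)["smd"].max()
    assert pre > 0.1
    assert post < pre
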