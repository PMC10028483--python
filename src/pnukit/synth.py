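"""Synthetic longitudinal claims with known causal structure.

The generator emulates the data environment of a large US commercial-claims
warehouse observed over a fixed study window: per-person enrollment spells,
coded diagnosis streams (type 2 / type 1 diabetes, osteoarthritis,
inflammatory arthritis, Charlson comorbidities), antidiabetic fill
sequences with switching between metformin and sulfonylurea, hip/knee
replacement procedures, and demographic covariates.  Osteoarthritis onset
is drawn from a piecewise-constant proportional-hazards model whose hazard
is multiplied by ``exp(true_log_hr_oa)`` while the person is covered by
metformin, so every downstream estimate can be checked against the
generative truth.

Design notes
------------
* All dates are integer days since 1970-01-01; intervals half-open.
* Event times are sampled by inversion of the piecewise cumulative hazard
  (exact under the proportional-hazards model the analysis layer assumes).
* Each simulated OA onset emits at least two OA codes >= 14 days apart so
  the claims phenotype can fire; unobserved onsets (second code would fall
  beyond the person's observation window) emit nothing.
* :func:`inject_confounding` reassigns the first-line drug with
  covariate-dependent probabilities while holding the marginal exposure
  split fixed, then re-simulates outcomes so that the causal structure
  remains consistent with the new exposure pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .claims import (
    ClaimsBundle,
    EDUCATION_LEVELS,
    RACE_LEVELS,
    REGION_LEVELS,
)
from .config import ConfigError, ICD10_SWITCH_DAY, SimConfig, _SIM_COVARIATES

__all__ = ["generate_population", "inject_confounding"]

# ------------------------------------------------------------------ vocabulary
# representative emission codes (ICD9, ICD10) per phenotype family
_T2D_CODE = ("250.00", "E11.9")
_T1D_CODE = ("250.01", "E10.9")
_OA_CODE = ("715.90", "M17.9")
_IA_CODE = ("714.0", "M05.9")
_JR_CPT = ("27130", "27447")

# Charlson categories the simulator seeds, with a representative code pair
# and the per-person prevalence.  The rheumatic category is deliberately
# absent (its codes are the inflammatory-arthritis exclusion phenotype) and
# uncomplicated diabetes is implied by the T2D stream itself.
_COMORBIDITY_EMISSIONS = {
    "myocardial_infarction": (("410.9", "I21.9"), 1, 0.04),
    "congestive_heart_failure": (("428.0", "I50.9"), 1, 0.05),
    "peripheral_vascular_disease": (("440.9", "I70.9"), 1, 0.05),
    "cerebrovascular_disease": (("434.91", "I63.9"), 1, 0.05),
    "dementia": (("290.0", "F03.90"), 1, 0.02),
    "chronic_pulmonary_disease": (("496", "J44.9"), 1, 0.08),
    "peptic_ulcer_disease": (("533.90", "K27.9"), 1, 0.03),
    "mild_liver_disease": (("571.5", "K74.60"), 1, 0.03),
    "diabetes_with_complication": (("250.42", "E11.22"), 2, 0.10),
    "hemiplegia_paraplegia": (("342.90", "G81.90"), 2, 0.01),
    "renal_disease": (("585.9", "N18.9"), 2, 0.05),
    "malignancy": (("185", "C61"), 2, 0.05),
    "moderate_severe_liver_disease": (("572.2", "K72.10"), 3, 0.01),
    "metastatic_solid_tumor": (("197.0", "C78.00"), 6, 0.01),
    "aids_hiv": (("042", "B20"), 6, 0.003),
}
# hierarchy pairs relevant to the emitted categories
_EMIT_HIERARCHY = (
    ("mild_liver_disease", "moderate_severe_liver_disease"),
    ("malignancy", "metastatic_solid_tumor"),
)

_RACE_P = (0.043, 0.135, 0.129, 0.673, 0.020)
_REGION_P = (0.229, 0.086, 0.457, 0.225, 0.003)
_EDU_P = (0.009, 0.339, 0.533, 0.115, 0.004)
_P_MALE = 0.582
_AGE_MEAN, _AGE_SD = 62.0, 11.5
_VISITS_MEAN = 7.0


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """0..k_i-1 concatenated over groups with sizes counts."""
    total = int(counts.sum())
    if total == 0:
        return np.zeros(0, dtype=np.int64)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    return np.arange(total) - offsets


def _year_of(days: np.ndarray) -> np.ndarray:
    return pd.to_datetime(np.asarray(days, dtype="int64"), unit="D").year.to_numpy()


def _code_rows(person_id, dates, code_pair):
    dates = np.asarray(dates, dtype=np.int64)
    icd10 = dates >= ICD10_SWITCH_DAY
    return pd.DataFrame(
        {
            "person_id": np.asarray(person_id, dtype=np.int64),
            "service_date": dates,
            "code_system": np.where(icd10, "ICD10", "ICD9"),
            "code": np.where(icd10, code_pair[1], code_pair[0]),
        }
    )


def generate_population(config: SimConfig) -> ClaimsBundle:
    """Generate a :class:`ClaimsBundle` from the configured study conditions.

    Identical config (including seed) yields identical output.
    """
    if not isinstance(config, SimConfig):
        raise ConfigError("config must be a SimConfig")
    if config.n_persons == 0:
        bundle = ClaimsBundle.empty()
        bundle.sim_state = _empty_state()
        return bundle

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    base, state = _build_base(config, rng)
    out_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    bundle = _simulate_outcomes(base, state, config, out_rng)
    bundle.validate(config.study_start, config.study_end)
    return bundle


def inject_confounding(bundle: ClaimsBundle, config: SimConfig) -> ClaimsBundle:
    """Reassign first-line drug classes with covariate-dependent channeling.

    The log-odds of starting on a sulfonylurea are shifted by
    ``config.confounding_strength`` (keys: age, sex_male, charlson, visits);
    the intercept is calibrated so the marginal sulfonylurea share equals
    the pre-call share (exact count preservation).  Outcomes (OA and joint
    replacement events) are re-simulated under the new exposure pattern.
    """
    for k in config.confounding_strength:
        if k not in _SIM_COVARIATES:
            raise ConfigError(f"confounding_strength: unknown covariate {k!r}")
    state = bundle.sim_state
    if state is None or "t0" not in getattr(state, "columns", ()):
        raise ConfigError("bundle lacks simulator state; use generate_population output")
    if not len(state):
        return bundle

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    state = state.copy()
    beta = config.confounding_strength
    x = (
        beta.get("age", 0.0) * (state["age"].to_numpy() - _AGE_MEAN)
        + beta.get("sex_male", 0.0) * state["male"].to_numpy()
        + beta.get("charlson", 0.0) * state["charlson_true"].to_numpy()
        + beta.get("visits", 0.0) * (state["visits"].to_numpy() - _VISITS_MEAN)
    )
    n_su = int(state["first_su"].sum())
    # covariate-graded assignment holding the marginal count fixed: persons
    # with the largest (log-odds shift + logistic noise) become su-first
    noise = rng.logistic(size=len(state))
    order = np.argsort(-(x + noise), kind="stable")
    new_first_su = np.zeros(len(state), dtype=bool)
    new_first_su[order[:n_su]] = True

    flipped = new_first_su != state["first_su"].to_numpy()
    state["first_su"] = new_first_su
    # exposed window = the metformin treatment segment under the new labels
    su = new_first_su
    sw = state["switch"].to_numpy().astype(bool)
    e1 = state["seg1_end"].to_numpy()
    s2 = state["seg2_start"].to_numpy()
    e2 = state["seg2_end"].to_numpy()
    t0 = state["t0"].to_numpy()
    exp_a = np.where(su, np.where(sw, s2, t0), t0)
    exp_b = np.where(su, np.where(sw, e2, t0), e1)
    state["exposed_start"], state["exposed_end"] = exp_a, exp_b

    # relabel study-drug fills of flipped persons (met <-> su)
    fills = bundle.fills.iloc[: int(state.attrs["n_base_fills"])].copy()
    flip_ids = set(state.loc[flipped, "person_id"])
    m = fills["person_id"].isin(flip_ids) & fills["drug_class"].isin(
        ["metformin", "sulfonylurea"]
    )
    fills.loc[m, "drug_class"] = fills.loc[m, "drug_class"].map(
        {"metformin": "sulfonylurea", "sulfonylurea": "metformin"}
    )

    base = ClaimsBundle(
        persons=bundle.persons,
        enrollment=bundle.enrollment,
        diagnoses=bundle.diagnoses.iloc[: int(state.attrs["n_base_dx"])],
        fills=fills,
        procedures=bundle.procedures.iloc[: int(state.attrs["n_base_proc"])],
        code_lists=bundle.code_lists,
    )
    out_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 3]))
    out = _simulate_outcomes(base, state, config, out_rng)
    out.validate(config.study_start, config.study_end)
    return out


# ----------------------------------------------------------------- internals
def _empty_state() -> pd.DataFrame:
    df = pd.DataFrame(
        columns=[
            "person_id", "t0", "obs_end", "age", "male", "visits",
            "charlson_true", "first_su", "switch",
            "seg1_end", "seg2_start", "seg2_end",
            "exposed_start", "exposed_end", "lp",
        ]
    )
    df.attrs.update(n_base_dx=0, n_base_proc=0, n_base_fills=0)
    return df


def _build_base(config: SimConfig, rng: np.random.Generator):
    n = config.n_persons
    start, end = config.study_start, config.study_end
    pid = np.arange(n, dtype=np.int64)

    male = rng.random(n) < _P_MALE
    race = rng.choice(np.array(RACE_LEVELS, dtype=object), size=n, p=_RACE_P)
    region = rng.choice(np.array(REGION_LEVELS, dtype=object), size=n, p=_REGION_P)
    edu = rng.choice(np.array(EDUCATION_LEVELS, dtype=object), size=n, p=_EDU_P)
    visits = np.round(rng.gamma(1.0, _VISITS_MEAN, size=n), 2)
    age_entry = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, size=n), 30, 95)

    # enrollment spell: starts early enough to leave room for lookback + follow-up
    latest_start = max(start + 1, end - 4 * 365)
    enroll_start = rng.integers(start, latest_start + 1, size=n)
    enroll_len = (2 * 365 + rng.exponential(8 * 365, size=n)).astype(np.int64)
    enroll_end = np.minimum(enroll_start + enroll_len, end)

    # qualifying T2D diagnosis and first antidiabetic fill
    t2d = enroll_start + 365 + (30 + rng.exponential(180, size=n)).astype(np.int64)
    t2d = np.minimum(t2d, enroll_end - 120)
    dx_first = rng.random(n) < config.p_dx_before_fill
    gap_fill = (1 + rng.exponential(90, size=n)).astype(np.int64)
    back_fill = (30 + rng.uniform(0, 170, size=n)).astype(np.int64)
    t0 = np.where(dx_first, t2d + gap_fill, t2d - back_fill)
    t0 = np.clip(t0, enroll_start, enroll_end - 60)

    # enrollment interruption: with prob enrollment_gap_prob the spell breaks
    # after treatment start (short breaks are administrative and bridgeable,
    # long breaks end observation)
    has_gap = (rng.random(n) < config.enrollment_gap_prob) & (enroll_end - t0 > 240)
    gap_at = t0 + 30 + (rng.random(n) * (enroll_end - t0 - 200).clip(1)).astype(np.int64)
    long_gap = rng.random(n) < 0.6
    gap_len = np.where(long_gap, 60 + rng.integers(0, 240, size=n), 5 + rng.integers(0, 25, size=n))
    obs_end = np.where(has_gap & long_gap, gap_at, enroll_end)

    birth_year = _year_of(t0) - np.round(age_entry).astype(int)
    age_idx = _year_of(t0) - birth_year  # integer age at treatment start

    persons = pd.DataFrame(
        {
            "person_id": pid,
            "birth_year": birth_year,
            "sex": np.where(male, "male", "female"),
            "race_ethnicity": race,
            "region": region,
            "education": edu,
            "outpatient_visits_per_year": visits,
        }
    )

    spells = [
        pd.DataFrame(
            {
                "person_id": pid[~(has_gap)],
                "spell_start": enroll_start[~has_gap],
                "spell_end": enroll_end[~has_gap],
            }
        ),
        pd.DataFrame(
            {
                "person_id": pid[has_gap],
                "spell_start": enroll_start[has_gap],
                "spell_end": gap_at[has_gap],
            }
        ),
        pd.DataFrame(
            {
                "person_id": pid[has_gap],
                "spell_start": np.minimum(gap_at + gap_len, enroll_end)[has_gap],
                "spell_end": enroll_end[has_gap],
            }
        ),
    ]
    enrollment = pd.concat(spells, ignore_index=True)
    enrollment = enrollment[enrollment["spell_start"] < enrollment["spell_end"]]
    enrollment = enrollment.sort_values(["person_id", "spell_start"]).reset_index(drop=True)

    # ---------------------------------------------------------- treatment
    supply = int(round(config.days_supply_mean))
    first_su = rng.random(n) < config.p_first_su
    p_switch = np.where(first_su, config.p_switch_su_to_met, config.p_switch_met_to_su)
    switch = rng.random(n) < p_switch
    dur1 = (30 + rng.exponential(config.treatment_duration_mean_days, size=n)).astype(np.int64)
    dur2 = (30 + rng.exponential(config.treatment_duration_mean_days, size=n)).astype(np.int64)

    seg1_start = t0
    seg1_stop = np.minimum(seg1_start + dur1, obs_end)
    n1 = np.ceil((seg1_stop - seg1_start).clip(0) / supply).astype(np.int64)
    seg1_end = seg1_start + n1 * supply  # coverage exhaustion of segment 1

    seg2_start = np.where(switch, seg1_end, 0)
    seg2_stop = np.where(switch, np.minimum(seg2_start + dur2, obs_end), 0)
    n2 = np.where(switch, np.ceil((seg2_stop - seg2_start).clip(0) / supply), 0).astype(np.int64)
    switch = switch & (n2 > 0)
    n2 = np.where(switch, n2, 0)
    seg2_end = np.where(switch, seg2_start + n2 * supply, 0)

    cls1 = np.where(first_su, "sulfonylurea", "metformin")
    cls2 = np.where(first_su, "metformin", "sulfonylurea")

    def _fills(seg_start, counts, classes):
        rep = np.repeat(np.arange(n), counts)
        k = _ragged_arange(counts)
        return pd.DataFrame(
            {
                "person_id": pid[rep],
                "fill_date": seg_start[rep] + k * supply,
                "drug_class": classes[rep],
                "days_supply": supply,
            }
        )

    fills = [_fills(seg1_start, n1, cls1), _fills(seg2_start, n2, cls2)]

    # exclusion fodder: same-day start of both drugs, combination products,
    # and other antidiabetic drugs (also a follow-up censoring event)
    same_day = rng.random(n) < config.p_same_day_start
    fills.append(
        pd.DataFrame(
            {
                "person_id": pid[same_day],
                "fill_date": t0[same_day],
                "drug_class": cls2[same_day],
                "days_supply": supply,
            }
        )
    )
    combo = rng.random(n) < config.p_combination_fill
    combo_date = np.clip(t0 + rng.integers(0, 300, size=n), None, obs_end - 1)
    fills.append(
        pd.DataFrame(
            {
                "person_id": pid[combo],
                "fill_date": combo_date[combo],
                "drug_class": "combination_met_su",
                "days_supply": supply,
            }
        )
    )
    other = rng.random(n) < config.p_other_antidiabetic
    other_date = np.clip(t0 + 30 + rng.integers(0, 600, size=n), None, obs_end - 1)
    fills.append(
        pd.DataFrame(
            {
                "person_id": pid[other],
                "fill_date": other_date[other],
                "drug_class": "other_antidiabetic",
                "days_supply": supply,
            }
        )
    )
    fills = pd.concat(fills, ignore_index=True)
    fills = fills.sort_values(["person_id", "fill_date"], kind="stable").reset_index(drop=True)

    # ---------------------------------------------------------- diagnoses
    dx_parts = []
    # T2D stream: first code at t2d, a confirming code >= 14 days later for
    # most persons (a small minority never meets the two-code phenotype)
    confirm = rng.random(n) < 0.97
    gap2 = 14 + rng.exponential(20, size=n).astype(np.int64)
    second = np.minimum(t2d + gap2, enroll_end - 1)
    confirm &= second - t2d >= 14
    dx_parts.append(_code_rows(pid, t2d, _T2D_CODE))
    dx_parts.append(_code_rows(pid[confirm], second[confirm], _T2D_CODE))
    third = rng.random(n) < 0.5
    third_date = np.minimum(second + 60, enroll_end - 1)
    keep3 = third & confirm
    dx_parts.append(_code_rows(pid[keep3], third_date[keep3], _T2D_CODE))

    t1d = rng.random(n) < config.p_t1d
    t1d_date = np.clip(t2d + rng.integers(-200, 200, size=n), enroll_start, enroll_end - 1)
    dx_parts.append(_code_rows(pid[t1d], t1d_date[t1d], _T1D_CODE))

    # prevalent OA / inflammatory arthritis (exclusion phenotypes)
    prev_oa = rng.random(n) < config.p_prevalent_oa
    poa1 = np.clip(t0 - rng.integers(100, 600, size=n), enroll_start, None)
    dx_parts.append(_code_rows(pid[prev_oa], poa1[prev_oa], _OA_CODE))
    dx_parts.append(_code_rows(pid[prev_oa], (poa1 + 20)[prev_oa], _OA_CODE))
    ia = rng.random(n) < config.p_inflammatory_arthritis
    ia_date = np.clip(t0 - rng.integers(0, 400, size=n), enroll_start, None)
    dx_parts.append(_code_rows(pid[ia], ia_date[ia], _IA_CODE))

    # Charlson comorbidity history before treatment start
    charlson_true = np.zeros(n)
    emitted = {}
    for cat, (codes, weight, prob) in _COMORBIDITY_EMISSIONS.items():
        has = rng.random(n) < prob
        when = enroll_start + (rng.random(n) * (t0 - enroll_start).clip(1)).astype(np.int64)
        dx_parts.append(_code_rows(pid[has], when[has], codes))
        emitted[cat] = has
    # generative score under the scoring hierarchy (+1/+2 for the diabetes
    # categories that the T2D stream itself implies)
    for cat, (codes, weight, prob) in _COMORBIDITY_EMISSIONS.items():
        counts = emitted[cat].astype(float)
        for mild, severe in _EMIT_HIERARCHY:
            if cat == mild:
                counts = counts * (~emitted[severe])
        charlson_true += weight * counts
    charlson_true += np.where(emitted["diabetes_with_complication"], 0.0, 1.0)

    diagnoses = pd.concat(dx_parts, ignore_index=True)
    diagnoses = diagnoses.sort_values(
        ["person_id", "service_date"], kind="stable"
    ).reset_index(drop=True)

    procedures = pd.DataFrame(
        columns=["person_id", "service_date", "cpt_code"]
    ).astype({"person_id": np.int64, "service_date": np.int64, "cpt_code": str})

    # hazard linear predictor on the covariates the analysis layer adjusts for
    eff = config.covariate_effects
    lp = (
        eff.get("age", 0.0) * (age_idx - _AGE_MEAN)
        + eff.get("sex_male", 0.0) * male
        + eff.get("charlson", 0.0) * charlson_true
        + eff.get("visits", 0.0) * (visits - _VISITS_MEAN)
    )

    exp_a = np.where(first_su, np.where(switch, seg2_start, t0), t0)
    exp_b = np.where(first_su, np.where(switch, seg2_end, t0), np.minimum(seg1_end, np.where(switch, seg2_start, seg1_end)))

    state = pd.DataFrame(
        {
            "person_id": pid,
            "t0": t0,
            "obs_end": obs_end,
            "age": age_idx.astype(float),
            "male": male.astype(float),
            "visits": visits,
            "charlson_true": charlson_true,
            "first_su": first_su,
            "switch": switch,
            "seg1_end": seg1_end,
            "seg2_start": seg2_start,
            "seg2_end": seg2_end,
            "exposed_start": exp_a,
            "exposed_end": exp_b,
            "lp": lp,
        }
    )
    state.attrs.update(
        n_base_dx=len(diagnoses), n_base_proc=len(procedures), n_base_fills=len(fills)
    )
    bundle = ClaimsBundle(
        persons=persons,
        enrollment=enrollment,
        diagnoses=diagnoses,
        fills=fills,
        procedures=procedures,
    )
    return bundle, state


def _simulate_outcomes(
    base: ClaimsBundle, state: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> ClaimsBundle:
    """Append OA diagnosis codes and joint-replacement procedures to a base bundle.

    OA onset follows a piecewise-constant hazard: ``baseline_oa_rate`` per
    person-year times ``exp(lp)``, times ``exp(true_log_hr_oa)`` inside the
    person's metformin-covered window; sampling is exact by inversion of
    the cumulative hazard over [t0, obs_end).
    """
    n = len(state)
    t0 = state["t0"].to_numpy(dtype=np.int64)
    obs_end = state["obs_end"].to_numpy(dtype=np.int64)
    a = np.clip(state["exposed_start"].to_numpy(dtype=np.int64), t0, obs_end)
    b = np.clip(state["exposed_end"].to_numpy(dtype=np.int64), a, obs_end)

    h0 = (config.baseline_oa_rate / 365.25) * np.exp(state["lp"].to_numpy())
    m = np.exp(config.true_log_hr_oa)
    H1 = h0 * (a - t0)
    H2 = h0 * m * (b - a)
    H3 = h0 * (obs_end - b)
    e = rng.exponential(size=n)
    onset = np.full(n, -1, dtype=np.int64)
    in1 = e < H1
    in2 = ~in1 & (e < H1 + H2)
    in3 = ~in1 & ~in2 & (e < H1 + H2 + H3)
    with np.errstate(divide="ignore", invalid="ignore"):
        onset[in1] = t0[in1] + (e[in1] / h0[in1]).astype(np.int64)
        onset[in2] = a[in2] + ((e[in2] - H1[in2]) / (h0[in2] * m)).astype(np.int64)
        onset[in3] = b[in3] + ((e[in3] - H1[in3] - H2[in3]) / h0[in3]).astype(np.int64)

    # second (confirming) OA code; onsets whose confirmation cannot be
    # observed inside the person's window are latent and emit nothing
    gap = 14 + rng.exponential(15, size=n).astype(np.int64)
    cand = onset >= 0
    second = onset + np.where(onset + gap < obs_end, gap, 14)
    case = cand & (second < obs_end)
    onset_d = onset[case]
    second_d = second[case]
    pid = state["person_id"].to_numpy()[case]

    dx_parts = [base.diagnoses]
    dx_parts.append(_code_rows(pid, onset_d, _OA_CODE))
    dx_parts.append(_code_rows(pid, second_d, _OA_CODE))
    extra = rng.random(case.sum()) < 0.5
    extra_date = second_d + 30
    keep = extra & (extra_date < obs_end[case])
    dx_parts.append(_code_rows(pid[keep], extra_date[keep], _OA_CODE))
    diagnoses = pd.concat(dx_parts, ignore_index=True)

    # joint replacement after OA onset
    jr_wait = rng.exponential(365.25 / max(config.jr_rate_given_oa, 1e-12), size=n)
    jr_date = onset + jr_wait.astype(np.int64)
    jr = case & (jr_date < obs_end)
    jr_code = rng.choice(np.array(_JR_CPT, dtype=object), size=n)
    proc = pd.DataFrame(
        {
            "person_id": state["person_id"].to_numpy()[jr],
            "service_date": jr_date[jr],
            "cpt_code": jr_code[jr],
        }
    )
    procedures = pd.concat([base.procedures, proc], ignore_index=True)

    new_state = state.copy()
    new_state["oa_onset"] = np.where(case, onset, -1)
    new_state["jr_date"] = np.where(jr, jr_date, -1)
    new_state.attrs.update(state.attrs)

    out = ClaimsBundle(
        persons=base.persons,
        enrollment=base.enrollment,
        diagnoses=diagnoses,
        fills=base.fills,
        procedures=procedures,
        code_lists=base.code_lists,
        sim_state=new_state,
    )
    return out
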