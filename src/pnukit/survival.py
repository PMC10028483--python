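"""Incidence, rate-ratio, Cox proportional-hazards, and Kaplan-Meier
analyses on resolved cohort records.

Time at risk runs from ``followup_start`` (index + 90-day landmark) to the
endpoint-specific ``followup_end``; person-years are days / 365.25.
Incidence rates are reported per 1000 person-years with log-scale Wald
95% CIs; Cox models use Efron tie handling (day-granular claims data are
heavily tied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims import ValidationError

__all__ = [
    "IncidenceResult",
    "RateRatioResult",
    "HazardResult",
    "KMCurve",
    "AnalysisResult",
    "person_time",
    "incidence_rate",
    "rate_ratio",
    "cox_model",
    "km_curve",
    "stratified_analysis",
    "analyze",
    "simulate_two_arm_exponential",
]

_Z = 1.959963984540054  # two-sided 95% normal quantile

#: adjustment covariates of the outcome models
COX_COVARIATES = (
    "age", "sex", "race_ethnicity", "region", "education", "charlson", "visits",
)

_ENDPOINT_COLS = {
    "oa": ("event_oa", "followup_end"),
    "jr": ("event_jr", "followup_end_jr"),
}


@dataclass(frozen=True)
class IncidenceResult:
    group: str
    events: int
    person_years: float
    ir_per_1000py: float
    ci_low: float
    ci_high: float
    zero_event_flag: bool = False


@dataclass(frozen=True)
class RateRatioResult:
    irr: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class HazardResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    mode: str
    covariates: tuple
    ties: str = "efron"
    n: int = 0
    events: int = 0
    notes: str = ""


@dataclass
class KMCurve:
    times: dict
    survival: dict
    at_risk: dict

    def as_frame(self, group: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_years": self.times[group],
                "survival": self.survival[group],
                "at_risk": self.at_risk[group],
            }
        )


def _durations(records: pd.DataFrame, endpoint: str):
    try:
        event_col, end_col = _ENDPOINT_COLS[endpoint]
    except KeyError:
        raise ValidationError(f"unknown endpoint {endpoint!r}") from None
    days = records[end_col] - records["followup_start"]
    if (days < 0).any():
        raise ValidationError("negative follow-up duration")
    return days / 365.25, records[event_col].astype(bool)


def person_time(records: pd.DataFrame, endpoint: str = "oa") -> pd.DataFrame:
    """Events and person-years per group, measured from the landmark."""
    if not len(records):
        return pd.DataFrame(columns=["group", "events", "person_years"])
    years, events = _durations(records, endpoint)
    out = (
        pd.DataFrame({"group": records["group"], "years": years, "event": events})
        .groupby("group", sort=True)
        .agg(events=("event", "sum"), person_years=("years", "sum"))
        .reset_index()
    )
    out["events"] = out["events"].astype(int)
    return out


def incidence_rate(events: int, person_years: float, group: str = "") -> IncidenceResult:
    """Rate per 1000 person-years with a log-scale Wald 95% CI.

    With zero events the rate is 0 and the upper bound is the one-sided
    exact Poisson limit 3.69/PY (flagged).
    """
    if person_years <= 0:
        raise ValidationError("person_years must be positive")
    if events < 0:
        raise ValidationError("events must be non-negative")
    ir = 1000.0 * events / person_years
    if events == 0:
        return IncidenceResult(group, 0, person_years, 0.0, 0.0,
                               3.69 * 1000.0 / person_years, zero_event_flag=True)
    half = _Z / np.sqrt(events)
    return IncidenceResult(
        group, int(events), float(person_years), ir,
        ir * np.exp(-half), ir * np.exp(half),
    )


def rate_ratio(exposed: IncidenceResult, reference: IncidenceResult) -> RateRatioResult:
    """IRR (exposed / reference) with a log-scale Wald 95% CI."""
    if exposed.events == 0 or reference.events == 0:
        raise ValidationError(
            "IRR undefined with zero events in an arm; use exact methods"
        )
    irr = (exposed.events / exposed.person_years) / (
        reference.events / reference.person_years
    )
    half = _Z * np.sqrt(1.0 / exposed.events + 1.0 / reference.events)
    return RateRatioResult(float(irr), float(irr * np.exp(-half)), float(irr * np.exp(half)))


def _cox_design(records: pd.DataFrame, covariates: tuple) -> pd.DataFrame:
    """Expand the adjustment covariates against their reference levels."""
    refs = {
        "sex": "female",
        "race_ethnicity": "White",
        "region": "South",
        "education": "high school diploma",
    }
    out = pd.DataFrame(index=records.index)
    for cov in covariates:
        if cov == "visits":
            out["visits"] = records["visits"].astype(float)
        elif cov in refs:
            levels = [l for l in sorted(records[cov].dropna().unique()) if l != refs[cov]]
            for lv in levels:
                col = (records[cov] == lv).astype(float)
                # levels too rare to estimate are pooled into the reference
                if col.sum() >= 10:
                    out[f"{cov}_{lv}"] = col
        else:
            out[cov] = records[cov].astype(float)
    # a constant column carries no information and breaks the fit
    return out.loc[:, out.std() > 1e-12]


def cox_model(
    records: pd.DataFrame,
    covariates: tuple = COX_COVARIATES,
    mode: str = "crude",
    endpoint: str = "oa",
) -> HazardResult:
    """Cox PH hazard ratio for metformin vs sulfonylurea.

    ``mode='crude'`` fits exposure alone; ``mode='adjusted'`` adds the
    listed covariates with categorical terms expanded against their
    reference levels.  Efron approximation for ties; Wald CI and p-value.
    Matched pairs are treated as independent observations (no cluster
    variance), flagged in ``notes``.
    """
    from lifelines import CoxPHFitter

    years, events = _durations(records, endpoint)
    exposed = (records["group"] == "metformin").astype(float)
    for arm, name in ((1.0, "metformin"), (0.0, "sulfonylurea")):
        if not events[exposed == arm].any():
            raise ValidationError(f"no events in the {name} arm; likelihood is monotone")
    df = pd.DataFrame({"T": years, "E": events.astype(int), "metformin": exposed})
    used: tuple = ()
    if mode == "adjusted":
        design = _cox_design(records, covariates)
        df = pd.concat([df.reset_index(drop=True), design.reset_index(drop=True)], axis=1)
        used = tuple(design.columns)
    elif mode != "crude":
        raise ValidationError("mode must be 'crude' or 'adjusted'")
    # day-granular data can contain zero-length event durations; lifelines
    # requires strictly positive times
    df.loc[df["T"] <= 0, "T"] = 0.5 / 365.25
    notes = "matched pairs treated as independent; " if "pair_id" in records else ""
    cph = None
    for penalizer in (0.0, 1e-3, 1e-1):
        try:
            fitter = CoxPHFitter(penalizer=penalizer)
            fitter.fit(df, duration_col="T", event_col="E", show_progress=False)
            cph = fitter
            if penalizer:
                notes += f"ridge penalizer {penalizer} (separation in adjustment terms)"
            break
        except Exception:
            continue
    if cph is None:
        raise ValidationError("Cox model failed to converge even with ridge penalty")
    row = cph.summary.loc["metformin"]
    return HazardResult(
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p_value=float(row["p"]),
        mode=mode,
        covariates=used,
        n=len(df),
        events=int(df["E"].sum()),
        notes=notes.rstrip("; "),
    )


def km_curve(records: pd.DataFrame, by: str = "group", endpoint: str = "oa") -> KMCurve:
    """Product-limit survival curves (one per level of ``by``)."""
    from lifelines import KaplanMeierFitter

    years, events = _durations(records, endpoint)
    times, surv, risk = {}, {}, {}
    for level in sorted(records[by].unique()):
        sel = (records[by] == level).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(years[sel], events[sel])
        sf = kmf.survival_function_.iloc[:, 0]
        times[level] = sf.index.to_numpy()
        surv[level] = sf.to_numpy()
        risk[level] = kmf.event_table["at_risk"].reindex(sf.index).to_numpy()
    return KMCurve(times=times, survival=surv, at_risk=risk)


def stratified_analysis(
    matched_records: pd.DataFrame,
    covariates: tuple = COX_COVARIATES,
    endpoint: str = "oa",
    mode: str = "adjusted",
) -> dict:
    """Cox results per prior-metformin stratum of the matched pairs.

    Empty strata (or strata where the model is inestimable) are skipped
    and reported under ``skipped``.
    """
    out: dict = {"skipped": []}
    for stratum in ("su_with_prior_metformin", "su_without_prior_metformin"):
        sub = matched_records[matched_records["stratum"] == stratum]
        if not len(sub):
            out["skipped"].append((stratum, "empty stratum"))
            continue
        try:
            out[stratum] = cox_model(sub, covariates, mode=mode, endpoint=endpoint)
        except (ValidationError, Exception) as exc:  # noqa: BLE001 - logged, not fatal
            out["skipped"].append((stratum, str(exc)))
    return out


@dataclass
class AnalysisResult:
    """Bundle of everything the analysis layer reports for one cohort."""

    incidence: dict
    rate_ratios: dict
    hazard_ratios: dict
    km: KMCurve | None = None
    balance: pd.DataFrame | None = None
    stratified: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out: dict = {}
        for ep, by_group in self.incidence.items():
            for g, ir in by_group.items():
                out[f"{ep}_ir_{g}"] = {
                    "events": ir.events,
                    "person_years": round(ir.person_years, 1),
                    "ir_per_1000py": round(ir.ir_per_1000py, 2),
                    "ci": [round(ir.ci_low, 2), round(ir.ci_high, 2)],
                }
        for ep, rr in self.rate_ratios.items():
            out[f"{ep}_irr"] = {
                "irr": round(rr.irr, 3),
                "ci": [round(rr.ci_low, 3), round(rr.ci_high, 3)],
            }
        for key, hr in self.hazard_ratios.items():
            out[f"{key}_hr"] = {
                "hr": round(hr.hr, 3),
                "ci": [round(hr.ci_low, 3), round(hr.ci_high, 3)],
                "p": round(hr.p_value, 5),
            }
        for stratum, hr in self.stratified.items():
            if isinstance(hr, HazardResult):
                out[f"stratified_{stratum}_hr"] = round(hr.hr, 3)
        return out


def analyze(
    records: pd.DataFrame,
    endpoints: tuple = ("oa", "jr"),
    covariates: tuple = COX_COVARIATES,
    with_km: bool = True,
    with_stratified: bool = None,
) -> AnalysisResult:
    """Full analysis layer on a (matched) cohort of records."""
    incidence, rate_ratios, hazards = {}, {}, {}
    for ep in endpoints:
        pt = person_time(records, ep).set_index("group")
        by_group = {
            g: incidence_rate(int(pt.loc[g, "events"]), float(pt.loc[g, "person_years"]), g)
            for g in pt.index
        }
        incidence[ep] = by_group
        if {"metformin", "sulfonylurea"} <= set(by_group):
            try:
                rate_ratios[ep] = rate_ratio(
                    by_group["metformin"], by_group["sulfonylurea"]
                )
            except ValidationError:
                pass
        for mode in ("crude", "adjusted"):
            try:
                hazards[f"{ep}_{mode}"] = cox_model(records, covariates, mode, ep)
            except ValidationError:
                pass
    km = km_curve(records) if with_km and len(records) else None
    if with_stratified is None:
        with_stratified = "stratum" in records.columns
    strat = (
        {
            k: v
            for k, v in stratified_analysis(records, covariates).items()
            if isinstance(v, HazardResult)
        }
        if with_stratified
        else {}
    )
    from .matching import balance_table

    bal = balance_table(records) if len(records) else None
    return AnalysisResult(
        incidence=incidence,
        rate_ratios=rate_ratios,
        hazard_ratios=hazards,
        km=km,
        balance=bal,
        stratified=strat,
    )


def simulate_two_arm_exponential(
    n_per_arm: int,
    log_hr: float,
    baseline_rate: float = 0.04,
    censor_rate: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group exponential survival data for calibration studies.

    Event times ~ Exp(rate * exp(log_hr * exposed)); independent
    exponential censoring.  Returns records in the cohort-record layout
    (followup_start/followup_end in days, event_oa, group) so they feed
    straight into :func:`cox_model` and :func:`person_time`.
    """
    rng = np.random.default_rng(seed)
    exposed = np.r_[np.ones(n_per_arm), np.zeros(n_per_arm)]
    rate = baseline_rate * np.exp(log_hr * exposed)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / censor_rate, size=2 * n_per_arm)
    t = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    days = np.maximum((t * 365.25).round().astype(np.int64), 1)
    return pd.DataFrame(
        {
            "group": np.where(exposed == 1, "metformin", "sulfonylurea"),
            "followup_start": 0,
            "followup_end": days,
            "event_oa": event,
            "followup_end_jr": days,
            "event_jr": False,
        }
    )
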