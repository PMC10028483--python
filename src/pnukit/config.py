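"""Configuration objects and calendar helpers.

All dates are carried internally as integer days since 1970-01-01 (the Unix
epoch) with half-open intervals [start, end); this keeps gap and duration
arithmetic unambiguous.  Public constructors accept ISO date strings,
``datetime.date`` objects, or day integers interchangeably.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "to_day",
    "from_day",
    "ICD10_SWITCH_DAY",
    "ConfigError",
    "SimConfig",
    "CodeListConfig",
    "RunConfig",
    "load_code_lists",
    "default_code_lists",
]

_EPOCH = _dt.date(1970, 1, 1)


def to_day(value) -> int:
    """Convert an ISO string / date / int to integer days since 1970-01-01."""
    if isinstance(value, bool):
        raise TypeError(f"not a date: {value!r}")
    if isinstance(value, int):
        return value
    if isinstance(value, _dt.datetime):
        value = value.date()
    if isinstance(value, _dt.date):
        return (value - _EPOCH).days
    if isinstance(value, str):
        return (_dt.date.fromisoformat(value) - _EPOCH).days
    raise TypeError(f"cannot interpret {value!r} as a date")


def from_day(day: int) -> _dt.date:
    return _EPOCH + _dt.timedelta(days=int(day))


#: First day on which claims carry ICD-10 rather than ICD-9 codes (US switch).
ICD10_SWITCH_DAY = to_day("2015-10-01")


class ConfigError(ValueError):
    """Raised when a configuration value is invalid; names the offending field."""


# covariate names the simulator understands, for hazards and for channeling
_SIM_COVARIATES = ("age", "sex_male", "charlson", "visits")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic claims generator.

    The defaults emulate a commercial-claims diabetes population observed
    December 2003 through December 2019: index age about 62 (SD 11.5),
    58% male, sulfonylurea a second-line minority drug, roughly one-year
    treatment persistence, and an osteoarthritis hazard of about 40 events
    per 1000 person-years off metformin.
    """

    n_persons: int = 1000
    study_start: int = to_day("2003-12-01")
    study_end: int = to_day("2019-12-31")
    seed: int = 0
    #: true exposure effect (log hazard ratio for OA while on metformin)
    true_log_hr_oa: float = 0.0
    #: baseline OA hazard, events per person-year, off metformin
    baseline_oa_rate: float = 0.040
    #: log-hazard coefficients on covariates (age per year centred at 62,
    #: sex_male indicator, charlson per point, visits per annual visit
    #: centred at 7); defaults reflect OA risk rising with age and
    #: comorbidity and being lower in men
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.02, "sex_male": -0.2, "charlson": 0.05}
    )
    #: log-odds effects of covariates on receiving sulfonylurea first
    confounding_strength: Mapping[str, float] = field(default_factory=dict)
    #: probability a metformin starter later switches to sulfonylurea
    p_switch_met_to_su: float = 0.15
    #: probability a sulfonylurea starter later switches to metformin
    p_switch_su_to_met: float = 0.10
    days_supply_mean: float = 30.0
    #: probability an enrollment spell is interrupted (early disenrollment)
    enrollment_gap_prob: float = 0.10
    #: probability of ever filling a non-study antidiabetic drug
    p_other_antidiabetic: float = 0.08
    #: hazard of hip/knee replacement after OA onset, events per person-year
    jr_rate_given_oa: float = 0.05
    #: marginal probability the first study drug is a sulfonylurea
    #: (metformin is first-line; sulfonylurea starters are a small minority)
    p_first_su: float = 0.10
    #: mean persistence on a study drug before stopping, days
    treatment_duration_mean_days: float = 365.0
    #: fraction of persons whose qualifying T2D diagnosis precedes the
    #: first antidiabetic fill
    p_dx_before_fill: float = 0.95
    #: probability of prevalent OA codes before treatment (exclusion fodder)
    p_prevalent_oa: float = 0.03
    p_inflammatory_arthritis: float = 0.02
    p_t1d: float = 0.01
    p_combination_fill: float = 0.01
    p_same_day_start: float = 0.005

    def __post_init__(self):
        object.__setattr__(self, "study_start", to_day(self.study_start))
        object.__setattr__(self, "study_end", to_day(self.study_end))
        if self.n_persons < 0:
            raise ConfigError("n_persons must be non-negative")
        if self.study_start >= self.study_end:
            raise ConfigError("study_start must precede study_end")
        for name in (
            "p_switch_met_to_su",
            "p_switch_su_to_met",
            "enrollment_gap_prob",
            "p_other_antidiabetic",
            "p_first_su",
            "p_dx_before_fill",
            "p_prevalent_oa",
            "p_inflammatory_arthritis",
            "p_t1d",
            "p_combination_fill",
            "p_same_day_start",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        for name in ("baseline_oa_rate", "jr_rate_given_oa"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.days_supply_mean < 1:
            raise ConfigError("days_supply_mean must be at least 1 day")
        if self.treatment_duration_mean_days <= 0:
            raise ConfigError("treatment_duration_mean_days must be positive")
        for m_name in ("covariate_effects", "confounding_strength"):
            for k in getattr(self, m_name):
                if k not in _SIM_COVARIATES:
                    raise ConfigError(
                        f"{m_name}: unknown covariate {k!r}; "
                        f"known covariates are {_SIM_COVARIATES}"
                    )

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class CodeListConfig:
    """Named diagnosis/procedure code sets used by the phenotyping layer.

    Codes are prefix sets on normalised codes (dots stripped, upper-case),
    keyed by code system, e.g. ``{"ICD9": ("25000",), "ICD10": ("E11",)}``.
    """

    t2d_codes: Mapping[str, tuple]
    t1d_codes: Mapping[str, tuple]
    oa_codes: Mapping[str, tuple]
    inflammatory_arthritis_codes: Mapping[str, tuple]
    joint_replacement_cpt: tuple
    #: drug classes counted as the two study drugs and their combinations
    study_drug_classes: tuple = ("metformin", "sulfonylurea")
    other_drug_classes: tuple = ("other_antidiabetic", "combination_met_su")

    def __post_init__(self):
        for name in (
            "t2d_codes",
            "t1d_codes",
            "oa_codes",
            "inflammatory_arthritis_codes",
        ):
            mapping = {
                sys: tuple(_normalize_code(c) for c in codes)
                for sys, codes in dict(getattr(self, name)).items()
            }
            if not any(mapping.values()):
                raise ConfigError(f"{name} must be non-empty")
            object.__setattr__(self, name, mapping)
        object.__setattr__(
            self, "joint_replacement_cpt", tuple(str(c) for c in self.joint_replacement_cpt)
        )
        if not self.joint_replacement_cpt:
            raise ConfigError("joint_replacement_cpt must be non-empty")
        for sys in self.t1d_codes:
            overlap = set(self.t1d_codes[sys]) & set(self.t2d_codes.get(sys, ()))
            if overlap:
                raise ConfigError(f"t1d and t2d code sets overlap in {sys}: {overlap}")


def _normalize_code(code: str) -> str:
    return str(code).replace(".", "").upper().strip()


def load_code_lists(path) -> CodeListConfig:
    """Load a :class:`CodeListConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _code_lists_from_mapping(raw)


def _code_lists_from_mapping(raw: Mapping) -> CodeListConfig:
    def codes(key):
        entry = raw[key]
        return {sys: tuple(v) for sys, v in entry.items()}

    return CodeListConfig(
        t2d_codes=codes("t2d"),
        t1d_codes=codes("t1d"),
        oa_codes=codes("oa"),
        inflammatory_arthritis_codes=codes("inflammatory_arthritis"),
        joint_replacement_cpt=tuple(raw["joint_replacement_cpt"]),
    )


def default_code_lists() -> CodeListConfig:
    """The packaged synthetic code vocabulary (a small, editable stand-in)."""
    ref = resources.files("pnukit.data").joinpath("default_codes.yaml")
    with ref.open() as fh:
        raw = yaml.safe_load(fh)
    return _code_lists_from_mapping(raw)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration (simulate -> cohort -> match -> analyze)."""

    sim: SimConfig = field(default_factory=SimConfig)
    design: str = "pnu"  # "pnu" (primary) or "caliper" (sensitivity)
    endpoints: tuple = ("oa", "jr")
    seed: int = 0
    out_dir: str = "pnu_run"
    # thresholds, all in days except the caliper (logit-PS SD multiples)
    t2d_separation_days: int = 14
    treatment_gap_days: int = 90
    enrollment_bridge_days: int = 30
    exposure_window_days: int = 15
    caliper_sd: float = 0.2
    charlson_map_path: str | None = None
    code_lists_path: str | None = None

    def __post_init__(self):
        if self.design not in ("pnu", "caliper"):
            raise ConfigError("design must be 'pnu' or 'caliper'")
        for name in (
            "t2d_separation_days",
            "treatment_gap_days",
            "enrollment_bridge_days",
            "exposure_window_days",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.caliper_sd <= 0:
            raise ConfigError("caliper_sd must be positive")
        for ep in self.endpoints:
            if ep not in ("oa", "jr"):
                raise ConfigError(f"unknown endpoint {ep!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        if "endpoints" in raw:
            raw["endpoints"] = tuple(raw["endpoints"])
        return cls(sim=sim, **raw)
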