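"""The raw-claims container: five tables plus the code-list configuration.

Tables are plain :class:`pandas.DataFrame` objects with documented columns;
all date columns are integer days since 1970-01-01 (see :mod:`pnukit.config`).

persons      person_id, birth_year, sex, race_ethnicity, region, education,
             outpatient_visits_per_year
enrollment   person_id, spell_start, spell_end          (half-open [start, end))
diagnoses    person_id, service_date, code_system, code
fills        person_id, fill_date, drug_class, days_supply
procedures   person_id, service_date, cpt_code
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .config import CodeListConfig, default_code_lists

__all__ = ["ClaimsBundle", "ValidationError"]

RACE_LEVELS = ("Asian", "Black", "Hispanic", "White", "unknown")
REGION_LEVELS = ("North Central", "Northeast", "South", "West", "unknown")
EDUCATION_LEVELS = (
    "<12th grade",
    "high school diploma",
    "<bachelor",
    ">=bachelor",
    "unknown",
)
DRUG_CLASSES = ("metformin", "sulfonylurea", "other_antidiabetic", "combination_met_su")
CODE_SYSTEMS = ("ICD9", "ICD10")

_TABLE_COLUMNS = {
    "persons": [
        "person_id",
        "birth_year",
        "sex",
        "race_ethnicity",
        "region",
        "education",
        "outpatient_visits_per_year",
    ],
    "enrollment": ["person_id", "spell_start", "spell_end"],
    "diagnoses": ["person_id", "service_date", "code_system", "code"],
    "fills": ["person_id", "fill_date", "drug_class", "days_supply"],
    "procedures": ["person_id", "service_date", "cpt_code"],
}


class ValidationError(ValueError):
    pass


@dataclass
class ClaimsBundle:
    persons: pd.DataFrame
    enrollment: pd.DataFrame
    diagnoses: pd.DataFrame
    fills: pd.DataFrame
    procedures: pd.DataFrame
    code_lists: CodeListConfig = field(default_factory=default_code_lists)
    #: private per-person latent state kept by the simulator so that
    #: confounding injection can re-simulate outcomes; not written to disk
    sim_state: Optional[pd.DataFrame] = None

    def validate(self, study_start: int | None = None, study_end: int | None = None):
        """Check referential integrity and the table invariants; raise on failure."""
        for name, cols in _TABLE_COLUMNS.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValidationError(f"{name} table missing columns {missing}")
        ids = set(self.persons["person_id"])
        if len(ids) != len(self.persons):
            raise ValidationError("duplicate person_id in persons")
        for name in ("enrollment", "diagnoses", "fills", "procedures"):
            df = getattr(self, name)
            if len(df) and not df["person_id"].isin(ids).all():
                raise ValidationError(f"{name} references unknown person_id")
        if len(self.enrollment) and (
            self.enrollment["spell_start"] > self.enrollment["spell_end"]
        ).any():
            raise ValidationError("enrollment spell_start > spell_end")
        if len(self.fills) and (self.fills["days_supply"] < 1).any():
            raise ValidationError("fills with days_supply < 1")
        if len(self.fills) and not self.fills["drug_class"].isin(DRUG_CLASSES).all():
            raise ValidationError("unknown drug_class in fills")
        if len(self.diagnoses) and not self.diagnoses["code_system"].isin(CODE_SYSTEMS).all():
            raise ValidationError("unknown code_system in diagnoses")
        if study_start is not None and study_end is not None:
            for name, col in (
                ("diagnoses", "service_date"),
                ("fills", "fill_date"),
                ("procedures", "service_date"),
            ):
                df = getattr(self, name)
                if len(df) and (
                    (df[col] < study_start) | (df[col] > study_end)
                ).any():
                    raise ValidationError(f"{name}.{col} outside the study window")
        return self

    # ------------------------------------------------------------------ I/O
    def write(self, directory):
        """Write the five tables as CSV files under ``directory``."""
        os.makedirs(directory, exist_ok=True)
        for name in _TABLE_COLUMNS:
            getattr(self, name).to_csv(os.path.join(directory, f"{name}.csv"), index=False)

    @classmethod
    def read(cls, directory, code_lists: CodeListConfig | None = None) -> "ClaimsBundle":
        tables = {
            name: pd.read_csv(os.path.join(directory, f"{name}.csv"))
            for name in _TABLE_COLUMNS
        }
        # an empty CSV loses dtypes; coerce the documented schema back
        for name, cols in _TABLE_COLUMNS.items():
            tables[name] = tables[name].reindex(columns=cols)
        if code_lists is None:
            code_lists = default_code_lists()
        return cls(code_lists=code_lists, **tables)

    @staticmethod
    def empty(code_lists: CodeListConfig | None = None) -> "ClaimsBundle":
        tables = {
            name: pd.DataFrame(columns=cols) for name, cols in _TABLE_COLUMNS.items()
        }
        if code_lists is None:
            code_lists = default_code_lists()
        return ClaimsBundle(code_lists=code_lists, **tables)

    def equals(self, other: "ClaimsBundle") -> bool:
        return all(
            getattr(self, name).reset_index(drop=True).equals(
                getattr(other, name).reset_index(drop=True)
            )
            for name in _TABLE_COLUMNS
        )
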