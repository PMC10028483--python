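"""Quan-Deyo Charlson comorbidity index from coded diagnosis history.

The score is the sum of the original Charlson weights over the distinct
Quan categories present strictly before a reference date, with the usual
hierarchy rules (only the severer of mild/moderate-severe liver disease,
uncomplicated/complicated diabetes, and any-malignancy/metastatic tumor
counts).  Matching is prefix-based on normalised codes (dots stripped,
upper-case), the standard convention for Quan mappings.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .claims import ValidationError
from .config import _normalize_code

__all__ = ["CharlsonMap", "load_charlson_map", "charlson_score", "charlson_scores"]


@dataclass(frozen=True)
class CharlsonMap:
    #: category -> weight
    weights: Mapping[str, int]
    #: code system ("ICD9"/"ICD10") -> {prefix -> category}
    prefixes: Mapping[str, Mapping[str, str]]
    #: (milder, severer) category pairs
    hierarchies: tuple

    def __post_init__(self):
        if any(w <= 0 for w in self.weights.values()):
            raise ValidationError("Charlson weights must be positive")
        cats = set(self.weights)
        for pair in self.hierarchies:
            if not set(pair) <= cats:
                raise ValidationError(f"hierarchy members {pair} not in category set")

    @property
    def max_prefix_len(self) -> int:
        return max(len(p) for m in self.prefixes.values() for p in m)


def load_charlson_map(path=None) -> CharlsonMap:
    """Load a Charlson map; the packaged Quan-Deyo fixture by default."""
    if path is None:
        ref = resources.files("pnukit.data").joinpath("charlson_quan.yaml")
        with ref.open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    weights, prefixes = {}, {"ICD9": {}, "ICD10": {}}
    for cat, entry in raw["categories"].items():
        weights[cat] = int(entry["weight"])
        for sys_key, sys_name in (("icd9", "ICD9"), ("icd10", "ICD10")):
            for pfx in entry.get(sys_key, ()):
                prefixes[sys_name][_normalize_code(pfx)] = cat
    hierarchies = tuple(tuple(pair) for pair in raw.get("hierarchies", ()))
    return CharlsonMap(weights=weights, prefixes=prefixes, hierarchies=hierarchies)


def _match_categories(codes: pd.Series, systems: pd.Series, cmap: CharlsonMap) -> pd.Series:
    """Map each (system, code) to a Charlson category (NaN when unmatched).

    Longest-prefix wins, so a specific prefix (e.g. I252) takes precedence
    over a shorter enclosing one.
    """
    bad = ~systems.isin(list(cmap.prefixes))
    if bad.any():
        raise ValidationError(
            f"unknown code system(s): {sorted(systems[bad].unique())}"
        )
    norm = codes.astype(str).str.replace(".", "", regex=False).str.upper().str.strip()
    out = pd.Series(np.nan, index=codes.index, dtype=object)
    for sys_name, table in cmap.prefixes.items():
        in_sys = systems == sys_name
        if not in_sys.any():
            continue
        sub = norm[in_sys]
        hit = pd.Series(np.nan, index=sub.index, dtype=object)
        for plen in range(1, cmap.max_prefix_len + 1):
            mapped = sub.str[:plen].map(table)
            hit = mapped.where(mapped.notna(), hit)
        out[in_sys] = hit
    return out


def _apply_hierarchy(present: set, cmap: CharlsonMap) -> set:
    keep = set(present)
    for mild, severe in cmap.hierarchies:
        if mild in keep and severe in keep:
            keep.discard(mild)
    return keep


def charlson_score(diagnoses: pd.DataFrame, as_of_date: int, cmap: CharlsonMap) -> int:
    """Score one person's diagnosis rows (columns service_date, code_system, code)."""
    prior = diagnoses[diagnoses["service_date"] < as_of_date]
    if not len(prior):
        return 0
    cats = _match_categories(prior["code"], prior["code_system"], cmap)
    present = _apply_hierarchy(set(cats.dropna()), cmap)
    return int(sum(cmap.weights[c] for c in present))


def charlson_scores(
    diagnoses: pd.DataFrame, as_of: pd.Series, cmap: CharlsonMap
) -> pd.Series:
    """Vectorised scores for many persons.

    ``as_of`` maps person_id -> reference date; returns person_id -> score
    (0 for persons with no matching history).
    """
    df = diagnoses[diagnoses["person_id"].isin(as_of.index)]
    out = pd.Series(0, index=as_of.index, dtype=int)
    if not len(df):
        return out
    cutoff = df["person_id"].map(as_of)
    df = df[df["service_date"] < cutoff]
    if not len(df):
        return out
    cats = _match_categories(df["code"], df["code_system"], cmap)
    hit = pd.DataFrame({"person_id": df["person_id"], "cat": cats}).dropna()
    hit = hit.drop_duplicates()
    # resolve hierarchies: drop the milder member where both are present
    for mild, severe in cmap.hierarchies:
        has_severe = set(hit.loc[hit["cat"] == severe, "person_id"])
        drop = (hit["cat"] == mild) & hit["person_id"].isin(has_severe)
        hit = hit[~drop]
    hit["w"] = hit["cat"].map(cmap.weights)
    sums = hit.groupby("person_id")["w"].sum()
    out.loc[sums.index] = sums.astype(int)
    return out
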