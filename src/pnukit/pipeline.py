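"""End-to-end orchestration: simulate -> cohort -> match -> analyze.

The pipeline is a pure function of (claims, configuration, seed): identical
inputs produce byte-identical outputs.  A provenance manifest records the
configuration hash, seed, software version, and the per-stage attrition
counts so the cohort flow can be reconstructed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import pandas as pd

from . import __version__
from .claims import ClaimsBundle
from .cohort import build_cohort, build_sensitivity_cohort
from .comorbidity import load_charlson_map
from .config import RunConfig
from .matching import (
    balance_table,
    build_exposure_sets,
    caliper_match,
    fit_time_conditional_ps,
    greedy_match,
)
from .survival import AnalysisResult, analyze
from .synth import generate_population, inject_confounding

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name."""


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(
    config: RunConfig,
    bundle: ClaimsBundle | None = None,
    write: bool = True,
) -> tuple[AnalysisResult, dict]:
    """Execute all stages; returns (AnalysisResult, manifest).

    When ``bundle`` is None, synthetic claims are generated from
    ``config.sim`` (with confounding injected if configured).  With
    ``write=True`` the cohort, matched records, balance table, KM data,
    results summary, and manifest are written under ``config.out_dir``.
    """
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    charlson_map = load_charlson_map(config.charlson_map_path)

    if bundle is None:
        sim = config.sim.with_(seed=config.seed)
        bundle = _stage("simulate")(generate_population)(sim)
        if any(v != 0 for v in sim.confounding_strength.values()):
            bundle = _stage("simulate")(inject_confounding)(bundle, sim)
    manifest["stages"]["claims"] = {
        name: int(len(getattr(bundle, name)))
        for name in ("persons", "enrollment", "diagnoses", "fills", "procedures")
    }

    study_end = config.sim.study_end
    if config.design == "pnu":
        records, attrition = _stage("cohort")(build_cohort)(
            bundle,
            study_end,
            t2d_separation_days=config.t2d_separation_days,
            gap_days=config.treatment_gap_days,
            bridge_days=config.enrollment_bridge_days,
            charlson_map=charlson_map,
        )
        manifest["stages"]["cohort"] = attrition
        sets = _stage("match")(build_exposure_sets)(records, config.exposure_window_days)
        ps = _stage("match")(fit_time_conditional_ps)(sets, seed=config.seed)
        matched = _stage("match")(greedy_match)(sets, ps)
        manifest["stages"]["match"] = {
            "exposure_sets": len(sets),
            "pairs": len(matched),
            "unmatched_su": matched.n_unmatched,
            "ps_converged": ps.converged,
            "ps_used_ridge": ps.used_ridge,
        }
    else:
        records, attrition = _stage("cohort")(build_sensitivity_cohort)(
            bundle,
            study_end,
            t2d_separation_days=config.t2d_separation_days,
            gap_days=config.treatment_gap_days,
            bridge_days=config.enrollment_bridge_days,
            charlson_map=charlson_map,
        )
        manifest["stages"]["cohort"] = attrition
        matched = _stage("match")(caliper_match)(
            records[records["group"] == "metformin"],
            records[records["group"] == "sulfonylurea"],
            caliper_sd=config.caliper_sd,
        )
        manifest["stages"]["match"] = {
            "pairs": len(matched),
            "unmatched_su": matched.n_unmatched,
        }

    matched_records = matched.records()
    result = _stage("analyze")(analyze)(matched_records, endpoints=config.endpoints)
    manifest["stages"]["analyze"] = {
        "records_analyzed": len(matched_records),
        **{
            f"{ep}_events_{g}": ir.events
            for ep, by_g in result.incidence.items()
            for g, ir in by_g.items()
        },
    }

    if write:
        _write_outputs(config, records, matched_records, result, manifest)
    return result, manifest


def _write_outputs(config, records, matched_records, result, manifest):
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    records.to_csv(os.path.join(out, "cohort.csv"), index=False)
    matched_records.to_csv(os.path.join(out, "matched.csv"), index=False)
    if result.balance is not None:
        result.balance.to_csv(os.path.join(out, "balance.csv"), index=False)
    if result.km is not None:
        for group in result.km.times:
            result.km.as_frame(group).to_csv(
                os.path.join(out, f"km_{group}.csv"), index=False
            )
    with open(os.path.join(out, "results.json"), "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
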