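"""End-to-end orchestration: inputs -> assignment -> classification -> summary.

The pipeline accepts the bundled worked-cohort fixture, a simulated cohort,
or user-supplied tables, and chains (optional) bead positivity calling,
specificity grouping, dual-mode DSA assignment, patient classification and
cohort summary, logging per-stage counts.  Every stage error aborts with
the stage name attached.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .engine import (
    DsaCall,
    assign_cohort,
    classify_cohort,
    summarize_cohort,
)
from .hla import Genotype
from .sab import PanelDefinition, Specificity

log = logging.getLogger("hladsa.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(name, exc) from exc


def calls_frame(calls_by_patient: Mapping[str, Sequence[DsaCall]]) -> pd.DataFrame:
    rows = []
    for pid, calls in calls_by_patient.items():
        for c in calls:
            rows.append({
                "patient_id": pid,
                "specificity": str(c.specificity),
                "locus": c.specificity.locus,
                "hla_class": c.specificity.hla_class,
                "mode": c.mode,
                "verdict": c.verdict.value,
                "reason_code": c.reason_code,
                "reason": c.reason,
            })
    return pd.DataFrame(rows)


def run_assignment(specs_by_patient: Mapping[str, Sequence[Specificity]],
                   donors_lr: Mapping[str, Genotype],
                   donors_hr: Mapping[str, Genotype],
                   panel: PanelDefinition,
                   patients: Sequence[str] | None = None,
                   outdir=None) -> dict:
    """Dual-mode assignment + classification + summary; optionally persisted.

    Returns ``{"summary": ..., "calls": DataFrame, "patients": DataFrame}``;
    with ``outdir`` set, writes calls.csv, patients.csv and summary.json.
    """
    n_specs = sum(len(v) for v in specs_by_patient.values())
    log.info("assign: %d specificities across %d patients",
             n_specs, len(specs_by_patient))
    calls = _stage("assign", assign_cohort, specs_by_patient,
                   donors_lr, donors_hr, panel, patients)
    classifications = _stage("classify", classify_cohort, calls)
    summary = _stage("summarize", summarize_cohort, classifications, calls)
    log.info("classify: %s", summary["patients"])
    patients_df = pd.DataFrame([{
        "patient_id": c.patient_id,
        "lr_dnDSA": int(c.lr_dnDSA),
        "hr_dnDSA": int(c.hr_dnDSA),
        "hr_class_I": int(c.hr_class_I),
        "hr_class_II": int(c.hr_class_II),
        "group": c.group,
    } for c in classifications])
    result = {"summary": summary, "calls": calls_frame(calls),
              "patients": patients_df}
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        result["calls"].to_csv(out / "calls.csv", index=False)
        patients_df.to_csv(out / "patients.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        log.info("wrote calls.csv, patients.csv, summary.json to %s", out)
    return result


def run_fixture_pipeline(outdir=None) -> dict:
    """The bundled worked cohort through the full assignment pipeline."""
    from .fixtures import load_fixture

    fb = _stage("load_fixture", load_fixture)
    log.info("fixture: %d patients", len(fb.patients))
    return run_assignment(fb.specs_by_patient, fb.donors_lr, fb.donors_hr,
                          fb.panel, fb.patients, outdir=outdir)


def run_simulated_pipeline(config, seed: int, outdir=None) -> dict:
    """Generate a synthetic cohort and push it through the pipeline."""
    from .simulate import generate_cohort

    cohort = _stage("simulate", generate_cohort, config, seed)
    log.info("simulate: %d pairs, %d beads",
             config.n_pairs, len(cohort.bead_frame))
    specs = _stage("call_beads", cohort.specificities)
    result = run_assignment(
        specs, cohort.donors_lr, cohort.donors_hr, cohort.panel,
        patients=list(cohort.clinical["patient_id"]), outdir=outdir)
    if outdir is not None:
        cohort.write(Path(outdir) / "inputs")
    result["cohort"] = cohort
    return result
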