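"""End-to-end estimation pipeline: impute -> weight -> estimate -> report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .catalog import ConditionCatalog, default_catalog, load_catalog
from .imputation import ImputationReport, impute_all
from .multimorbidity import multimorbidity_prevalence
from .prevalence import (
    compare_methods,
    encounter_prevalence,
    estimates_table,
    population_prevalence,
)
from .records import load_records
from .strata import StratumReference, load_stratum_reference
from .weighting import WeightSet, build_weight_set

logger = logging.getLogger("gpprev")


@dataclass
class PipelineResult:
    encounter: pd.DataFrame
    population: pd.DataFrame
    comparison: pd.DataFrame | None
    multimorbidity: pd.DataFrame
    imputation_report: ImputationReport
    weight_sets: dict = field(default_factory=dict)
    records: pd.DataFrame | None = None


def run_pipeline(
    records,
    reference,
    catalog: ConditionCatalog | str | Path | None = None,
    targets=None,
    methods=("old", "new"),
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Run imputation, weighting (old and/or new), prevalence and
    multimorbidity estimation; optionally write the tidy output bundle.

    ``records`` and ``reference`` may be paths or already-loaded objects.
    ``targets`` defaults to every chronic condition in the catalog plus the
    chapters it uses.
    """
    if catalog is None:
        catalog = default_catalog()
    elif not isinstance(catalog, ConditionCatalog):
        catalog = load_catalog(catalog)
    if not isinstance(records, pd.DataFrame):
        records = load_records(records, catalog)
    if not isinstance(reference, StratumReference):
        reference = load_stratum_reference(reference)

    df, report = impute_all(records, catalog)
    logger.info(
        "imputation: %d missing condition responses (%d reassigned from "
        "encounter, %d set to no conditions), %d missing visit counts",
        report.n_missing_condition,
        report.n_reassigned_from_encounter,
        report.n_assigned_no_conditions,
        report.n_missing_visits,
    )

    if targets is None:
        chronic = sorted(catalog.chronic_codes())
        chapters = sorted({catalog.chapter(c) for c in chronic})
        targets = chronic + chapters

    weight_sets: dict[str, WeightSet] = {
        m: build_weight_set(df, reference, m) for m in methods
    }
    for m, ws in weight_sets.items():
        logger.info("%s-method weights: B=%.4f, uncovered population share %.4g",
                    m, ws.b_constant, ws.uncovered_population_share)

    enc = estimates_table(
        encounter_prevalence(df, t, catalog) for t in targets
    )
    pop_rows = []
    for m, ws in weight_sets.items():
        for t in targets:
            pop_rows.append(population_prevalence(df, t, catalog, ws))
    pop = estimates_table(pop_rows)

    comparison = None
    if set(methods) >= {"old", "new"}:
        comparison = compare_methods(df, targets, reference, catalog)

    mm_parts = [multimorbidity_prevalence(df, catalog)]
    for m, ws in weight_sets.items():
        mm_parts.append(multimorbidity_prevalence(df, catalog, weight_set=ws))
    mm = pd.concat(mm_parts, ignore_index=True)

    result = PipelineResult(
        encounter=enc,
        population=pop,
        comparison=comparison,
        multimorbidity=mm,
        imputation_report=report,
        weight_sets=weight_sets,
        records=df,
    )
    if output_dir is not None:
        write_outputs(result, output_dir)
    return result


def write_outputs(result: PipelineResult, output_dir: str | Path) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.encounter.to_csv(out / "encounter_prevalence.csv", index=False)
    result.population.to_csv(out / "population_prevalence.csv", index=False)
    if result.comparison is not None:
        result.comparison.to_csv(out / "method_comparison.csv", index=False)
    result.multimorbidity.to_csv(out / "multimorbidity.csv", index=False)
    result.imputation_report.to_json(out / "imputation_report.json")
    audits = []
    for m, ws in result.weight_sets.items():
        audit = ws.weights.copy()
        audit.insert(0, "method", m)
        audit.insert(1, "b_constant", ws.b_constant)
        if result.records is not None:
            audit.insert(0, "patient_id", result.records.loc[audit.index, "patient_id"])
        audits.append(audit)
    if audits:
        pd.concat(audits).to_csv(out / "weight_audit.csv", index=False)
    meta = {
        "methods": sorted(result.weight_sets),
        "b_constant": {m: ws.b_constant for m, ws in result.weight_sets.items()},
        "n_records": int(len(result.records)) if result.records is not None else None,
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable config, for run logs."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
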