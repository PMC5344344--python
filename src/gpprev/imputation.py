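"""Missing-data rules applied before any weighting.

Two mechanisms are handled, in a fixed order:

1. *Missing chronic-condition response.* Patients who answered neither the
   "has chronic conditions" nor the "no chronic conditions" box are treated
   as having no chronic conditions — unless chronic conditions were managed
   at their sampled encounter, in which case those managed chronic
   conditions are assigned to the patient. This errs against overestimating
   prevalence.

2. *Missing visit count.* Patients whose 12-month GP visit count was not
   recorded receive the mean reported count among patients of the same
   10-year age band, same sex, and same chronic-condition count band
   (0, 1, 2, 3+). Cell means are kept fractional; the attendance weight
   C = B/A is a ratio and needs no integer A.

Condition-status imputation must run first: the visit-imputation cells are
defined by the (post-imputation) condition counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ConditionCatalog
from .multimorbidity import condition_counts
from .records import HAS, MISSING, NO


class ImputationError(ValueError):
    pass


@dataclass
class ImputationReport:
    """Audit trail of both imputation passes."""

    n_missing_condition: int = 0
    n_reassigned_from_encounter: int = 0
    n_assigned_no_conditions: int = 0
    n_missing_visits: int = 0
    #: (age band label, sex, count band) -> mean visits used for that cell.
    visit_imputation_cells: dict = field(default_factory=dict)
    #: fallback level used per imputed patient_id: "cell", "age_sex", "age", "global"
    visit_fallback_levels: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_missing_condition": self.n_missing_condition,
            "n_reassigned_from_encounter": self.n_reassigned_from_encounter,
            "n_assigned_no_conditions": self.n_assigned_no_conditions,
            "n_missing_visits": self.n_missing_visits,
            "visit_imputation_cells": {
                "|".join(map(str, k)): v
                for k, v in self.visit_imputation_cells.items()
            },
            "visit_fallback_levels": dict(self.visit_fallback_levels),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def impute_condition_status(
    df: pd.DataFrame, catalog: ConditionCatalog
) -> tuple[pd.DataFrame, ImputationReport]:
    """Resolve missing condition responses from encounter-managed problems.

    Idempotent: records with a non-missing response are never touched, and
    after one pass no response is missing.
    """
    df = df.copy()
    report = ImputationReport()
    miss = df["condition_response"] == MISSING
    report.n_missing_condition = int(miss.sum())
    if report.n_missing_condition == 0:
        return df, report

    chronic_managed = df.loc[miss, "encounter_managed"].map(catalog.chronic_subset)
    has_chronic = chronic_managed.map(bool)

    reassign = miss.copy()
    reassign.loc[miss] = has_chronic
    df.loc[reassign, "conditions"] = chronic_managed[has_chronic]
    df.loc[reassign, "condition_response"] = HAS

    to_none = miss & ~reassign
    df.loc[to_none, "conditions"] = [frozenset()] * int(to_none.sum())
    df.loc[to_none, "condition_response"] = NO

    report.n_reassigned_from_encounter = int(reassign.sum())
    report.n_assigned_no_conditions = int(to_none.sum())
    return df, report


def _age_band_label(age: float, width: int = 10) -> str | None:
    if pd.isna(age):
        return None
    lo = int(age // width) * width
    return f"{lo}-{lo + width - 1}"


def _count_band(k: int) -> str:
    return str(k) if k < 3 else "3+"


def impute_visits(
    df: pd.DataFrame, catalog: ConditionCatalog
) -> tuple[pd.DataFrame, ImputationReport]:
    """Fill missing visit counts with cell means.

    Cells are (10-year age band anchored at 0, sex, condition-count band).
    Empty cells fall back by collapsing, in order: the count band, then sex,
    then everything (global mean) — age, the strongest predictor of
    attendance, is preserved longest. If no level has donors the input is
    unusable and an :class:`ImputationError` is raised.
    """
    if (df["condition_response"] == MISSING).any():
        raise ImputationError(
            "condition-status imputation must run before visit imputation"
        )
    df = df.copy()
    report = ImputationReport()
    missing = df["reported_visits"].isna()
    report.n_missing_visits = int(missing.sum())
    if report.n_missing_visits == 0:
        return df, report

    donors = df[~missing]
    if donors.empty:
        raise ImputationError("no records with observed visit counts to impute from")

    k = condition_counts(df, catalog)
    band = df["age"].map(_age_band_label)
    cband = pd.Series([_count_band(int(x)) for x in k], index=df.index)

    d_visits = donors["reported_visits"]
    d_band = band[~missing]
    d_sex = donors["sex"]
    d_cband = cband[~missing]

    cell_means = d_visits.groupby([d_band, d_sex, d_cband]).mean()
    age_sex_means = d_visits.groupby([d_band, d_sex]).mean()
    age_means = d_visits.groupby([d_band]).mean()
    global_mean = float(d_visits.mean())

    filled = np.empty(int(missing.sum()))
    for j, idx in enumerate(df.index[missing]):
        key3 = (band[idx], df.at[idx, "sex"], cband[idx])
        pid = df.at[idx, "patient_id"]
        if key3 in cell_means.index and key3[0] is not None and not pd.isna(key3[1]):
            filled[j] = cell_means[key3]
            report.visit_imputation_cells.setdefault(key3, float(cell_means[key3]))
            report.visit_fallback_levels[pid] = "cell"
        elif (key3[0], key3[1]) in age_sex_means.index and key3[0] is not None:
            filled[j] = age_sex_means[(key3[0], key3[1])]
            report.visit_fallback_levels[pid] = "age_sex"
        elif key3[0] is not None and key3[0] in age_means.index:
            filled[j] = age_means[key3[0]]
            report.visit_fallback_levels[pid] = "age"
        else:
            filled[j] = global_mean
            report.visit_fallback_levels[pid] = "global"

    df.loc[missing, "reported_visits"] = filled
    df.loc[missing, "visits_imputed"] = True
    return df, report


def impute_all(
    df: pd.DataFrame, catalog: ConditionCatalog
) -> tuple[pd.DataFrame, ImputationReport]:
    """Both imputation passes in the required order, with a merged report."""
    df, rep_cond = impute_condition_status(df, catalog)
    df, rep_vis = impute_visits(df, catalog)
    rep_cond.n_missing_visits = rep_vis.n_missing_visits
    rep_cond.visit_imputation_cells = rep_vis.visit_imputation_cells
    rep_cond.visit_fallback_levels = rep_vis.visit_fallback_levels
    return df, rep_cond
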