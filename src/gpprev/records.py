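"""Patient encounter records: the sampled-patient table and its CSV I/O.

A record collection is a :class:`pandas.DataFrame` with one row per sampled
patient and columns

========================  =====================================================
patient_id                opaque identifier (string)
gp_id                     cluster identifier — the recording GP (string)
age                       age in years (float; NaN when missing)
sex                       ``"male"`` / ``"female"`` / NA
reported_visits           GP visits in the past 12 months *including the
                          sampled visit* (float >= 1; NaN when missing)
condition_response        ``"has_conditions"`` / ``"no_conditions"`` /
                          ``"missing"``
conditions                frozenset of condition codes
encounter_managed         frozenset of condition codes managed at the encounter
visits_imputed            bool — reported_visits was filled in by imputation
========================  =====================================================

The visit count includes the sampled visit, so a recorded value of 0 is a
recording error, not a valid observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ConditionCatalog, UnknownConditionError

RECORD_COLUMNS = [
    "patient_id",
    "gp_id",
    "age",
    "sex",
    "reported_visits",
    "condition_response",
    "conditions",
    "encounter_managed",
    "visits_imputed",
]

HAS = "has_conditions"
NO = "no_conditions"
MISSING = "missing"

_SEXES = {"male", "female"}


class RecordValidationError(ValueError):
    """One or more input rows violated the record invariants."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid encounter records:\n  " + "\n  ".join(problems)
        )


@dataclass(frozen=True)
class PatientRecord:
    """A single sampled encounter patient (convenience view of one row)."""

    patient_id: str
    gp_id: str
    age: float | None = None
    sex: str | None = None
    reported_visits: float | None = None
    condition_response: str = MISSING
    conditions: frozenset = field(default_factory=frozenset)
    encounter_managed: frozenset = field(default_factory=frozenset)
    visits_imputed: bool = False


def records_to_frame(records) -> pd.DataFrame:
    """Build the canonical DataFrame from an iterable of PatientRecord."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "gp_id": r.gp_id,
                "age": np.nan if r.age is None else float(r.age),
                "sex": r.sex,
                "reported_visits": (
                    np.nan if r.reported_visits is None else float(r.reported_visits)
                ),
                "condition_response": r.condition_response,
                "conditions": frozenset(r.conditions),
                "encounter_managed": frozenset(r.encounter_managed),
                "visits_imputed": bool(r.visits_imputed),
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PatientRecord(
                patient_id=row.patient_id,
                gp_id=row.gp_id,
                age=None if pd.isna(row.age) else float(row.age),
                sex=None if pd.isna(row.sex) else row.sex,
                reported_visits=(
                    None if pd.isna(row.reported_visits) else float(row.reported_visits)
                ),
                condition_response=row.condition_response,
                conditions=frozenset(row.conditions),
                encounter_managed=frozenset(row.encounter_managed),
                visits_imputed=bool(row.visits_imputed),
            )
        )
    return out


def _parse_codes(cell: str) -> frozenset[str]:
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    return frozenset(c.strip() for c in cell.split(";") if c.strip())


def load_records(path: str | Path, catalog: ConditionCatalog) -> pd.DataFrame:
    """Read and validate an encounter-record CSV.

    Rows violating the record invariants are reported with row-level
    diagnostics in a single :class:`RecordValidationError`; unknown condition
    codes are an error naming the code and row. Missing cells become explicit
    missing values (NaN / ``"missing"``), never empty strings.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {
        "patient_id",
        "gp_id",
        "age",
        "sex",
        "reported_visits",
        "condition_response",
        "conditions",
        "encounter_managed",
    }
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise RecordValidationError(
            [f"missing columns: {sorted(missing_cols)}"]
        )

    problems: list[str] = []
    rows = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):  # header = line 1
        ok = True

        age_s = row.age.strip()
        age = np.nan
        if age_s:
            try:
                age = float(age_s)
            except ValueError:
                problems.append(f"row {i}: age {age_s!r} is not a number")
                ok = False
            else:
                if age < 0:
                    problems.append(f"row {i}: age {age} is negative")
                    ok = False

        sex_s = row.sex.strip().lower()
        sex: str | None = None
        if sex_s:
            if sex_s in _SEXES:
                sex = sex_s
            else:
                problems.append(f"row {i}: sex {row.sex!r} not in {{male, female}}")
                ok = False

        visits_s = row.reported_visits.strip()
        visits = np.nan
        if visits_s:
            try:
                visits = float(visits_s)
            except ValueError:
                problems.append(
                    f"row {i}: reported_visits {visits_s!r} is not a number"
                )
                ok = False
            else:
                if visits < 1:
                    problems.append(
                        f"row {i}: reported_visits {visits_s} < 1 — the count "
                        f"includes the sampled visit, so it must be at least 1"
                    )
                    ok = False

        try:
            conditions = _parse_codes(row.conditions)
            catalog.validate_codes(conditions, row=i)
            managed = _parse_codes(row.encounter_managed)
            catalog.validate_codes(managed, row=i)
        except UnknownConditionError as e:
            problems.append(str(e))
            ok = False
            conditions = frozenset()
            managed = frozenset()

        resp_s = row.condition_response.strip().lower()
        if resp_s in {"yes", "y", HAS}:
            resp = HAS
        elif resp_s in {"no", "n", NO}:
            resp = NO
        elif resp_s in {"", MISSING, "na"}:
            resp = MISSING
        else:
            problems.append(
                f"row {i}: condition_response {row.condition_response!r} "
                f"not recognised"
            )
            ok = False
            resp = MISSING

        if resp == NO and conditions:
            problems.append(
                f"row {i}: condition_response is no_conditions but conditions "
                f"lists {sorted(conditions)}"
            )
            ok = False
        if resp == HAS and not conditions:
            problems.append(
                f"row {i}: condition_response is has_conditions but the "
                f"conditions field is empty"
            )
            ok = False
        # A blank response with a non-empty condition list is a filled form:
        # treat it as has_conditions rather than missing.
        if resp == MISSING and conditions:
            resp = HAS

        if ok:
            rows.append(
                {
                    "patient_id": row.patient_id.strip(),
                    "gp_id": row.gp_id.strip(),
                    "age": age,
                    "sex": sex,
                    "reported_visits": visits,
                    "condition_response": resp,
                    "conditions": conditions,
                    "encounter_managed": managed,
                    "visits_imputed": False,
                }
            )

    if problems:
        raise RecordValidationError(problems)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write records to CSV in the same layout :func:`load_records` reads."""
    out = df.copy()
    out["conditions"] = out["conditions"].map(lambda s: ";".join(sorted(s)))
    out["encounter_managed"] = out["encounter_managed"].map(
        lambda s: ";".join(sorted(s))
    )
    out["condition_response"] = out["condition_response"].replace({MISSING: ""})
    out["sex"] = out["sex"].fillna("")
    cols = [c for c in RECORD_COLUMNS if c != "visits_imputed"]
    out[cols].to_csv(path, index=False)
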