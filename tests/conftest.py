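import numpy as np
import pandas as pd
import pytest

from gpprev import (
    ConditionCatalog,
    PatientRecord,
    StratumReference,
    default_catalog,
    records_to_frame,
)
from gpprev.catalog import CatalogEntry


@pytest.fixture(scope="session")
def catalog() -> ConditionCatalog:
    return default_catalog()


@pytest.fixture(scope="session")
def tiny_catalog() -> ConditionCatalog:
    """A hand-sized catalog: three chronic conditions in three chapters,
    two sharing a chapter, plus one acute code."""
    return ConditionCatalog(
        {
            "hypertension": CatalogEntry("hypertension", "Hypertension", "K", True),
            "ihd": CatalogEntry("ihd", "Ischaemic heart disease", "K", True),
            "osteoarthritis": CatalogEntry("osteoarthritis", "Osteoarthritis", "L", True),
            "depression": CatalogEntry("depression", "Depression", "P", True),
            "acute_urti": CatalogEntry("acute_urti", "Acute URTI", "R", False),
        }
    )


@pytest.fixture(scope="session")
def two_strata() -> StratumReference:
    """Two broad strata per sex covering ages [0, 50) and [50, 100)."""
    return StratumReference(
        pd.DataFrame(
            {
                "sex": ["male", "male", "female", "female"],
                "age_low": [0.0, 50.0, 0.0, 50.0],
                "age_high": [50.0, 100.0, 50.0, 100.0],
                "population_share": [0.26, 0.24, 0.25, 0.25],
                "attender_share": [0.75, 0.95, 0.80, 0.97],
            }
        )
    )


def make_record(i, gp="gp1", age=40, sex="male", visits=4, conditions=(),
                managed=(), response=None):
    conditions = frozenset(conditions)
    if response is None:
        response = "has_conditions" if conditions else "no_conditions"
    return PatientRecord(
        patient_id=f"p{i}",
        gp_id=gp,
        age=age,
        sex=sex,
        reported_visits=visits,
        condition_response=response,
        conditions=conditions,
        encounter_managed=frozenset(managed),
    )


@pytest.fixture
def toy_records() -> pd.DataFrame:
    """Four patients, two GP clusters, both sexes and both broad age bands."""
    return records_to_frame(
        [
            make_record(1, gp="gpA", age=30, sex="male", visits=2,
                        conditions=["hypertension"]),
            make_record(2, gp="gpA", age=70, sex="male", visits=8,
                        conditions=["hypertension", "osteoarthritis"]),
            make_record(3, gp="gpB", age=25, sex="female", visits=1),
            make_record(4, gp="gpB", age=60, sex="female", visits=4,
                        conditions=["depression"]),
        ]
    )


def bruteforce_population_prevalence(records, strata_table, target_codes, method):
    """Independent term-by-term evaluation of the weighting algebra.

    Plain-Python re-derivation used as an oracle: B as the harmonic mean,
    C = B/A (or 1), stratum shares E from C, F = D/E, then
    sum(C*F*G*I) / sum(C*F). ``strata_table`` is a list of dicts with keys
    sex, age_low, age_high, population_share, attender_share.
    """
    pts = []
    for row in records.itertuples(index=False):
        s = None
        for j, st in enumerate(strata_table):
            if (
                row.sex == st["sex"]
                and not pd.isna(row.age)
                and st["age_low"] <= row.age < st["age_high"]
            ):
                s = j
        if s is None:
            continue
        pts.append(
            {
                "A": float(row.reported_visits),
                "stratum": s,
                "I": 1.0 if any(c in row.conditions for c in target_codes) else 0.0,
            }
        )
    n = len(pts)
    B = n / sum(1.0 / p["A"] for p in pts)
    for p in pts:
        p["C"] = B / p["A"] if method == "new" else 1.0
    totC = sum(p["C"] for p in pts)
    E = {}
    for p in pts:
        E[p["stratum"]] = E.get(p["stratum"], 0.0) + p["C"] / totC
    covered_D = sum(
        st["population_share"] for j, st in enumerate(strata_table) if j in E
    )
    F = {
        j: (strata_table[j]["population_share"] / covered_D) / E[j] for j in E
    }
    num = sum(
        p["C"] * F[p["stratum"]] * strata_table[p["stratum"]]["attender_share"] * p["I"]
        for p in pts
    )
    den = sum(p["C"] * F[p["stratum"]] for p in pts)
    return num / den
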