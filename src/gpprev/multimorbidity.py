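"""Multimorbidity measures: chronic-condition counts and body-system counts.

Multimorbidity is the co-occurrence of two or more chronic conditions in one
person, with no index condition. Complex multimorbidity additionally demands
that at least three different body systems are affected: three or more
chronic conditions spread over three or more ICPC-2 chapters. A body system
(chapter) is counted once per patient however many of its conditions the
patient has.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import ConditionCatalog


def _codes(record) -> Iterable[str]:
    # Accept a PatientRecord-like object, a DataFrame row, or a bare code set.
    if hasattr(record, "conditions"):
        return record.conditions
    return record


def condition_count(record, catalog: ConditionCatalog) -> int:
    """Number of distinct diagnosed *chronic* conditions on the record."""
    return len(catalog.chronic_subset(_codes(record)))


def body_system_count(record, catalog: ConditionCatalog) -> int:
    """Number of distinct ICPC-2 chapters covered by the record's chronic
    conditions; never exceeds :func:`condition_count`."""
    return len({catalog.chapter(c) for c in catalog.chronic_subset(_codes(record))})


def _band(k: int) -> str:
    return str(k) if k < 3 else "3+"


@dataclass(frozen=True)
class MultimorbidityClass:
    multimorbidity: bool
    complex_multimorbidity: bool
    count_band: str
    system_band: str


def classify(record, catalog: ConditionCatalog) -> MultimorbidityClass:
    """Multimorbidity flags and {0,1,2,3+} bands for one patient."""
    k = condition_count(record, catalog)
    s = body_system_count(record, catalog)
    return MultimorbidityClass(
        multimorbidity=k >= 2,
        complex_multimorbidity=k >= 3 and s >= 3,
        count_band=_band(k),
        system_band=_band(s),
    )


def condition_counts(df: pd.DataFrame, catalog: ConditionCatalog) -> np.ndarray:
    """Vector of chronic-condition counts, one per record row."""
    return df["conditions"].map(lambda s: condition_count(s, catalog)).to_numpy()


def body_system_counts(df: pd.DataFrame, catalog: ConditionCatalog) -> np.ndarray:
    return df["conditions"].map(lambda s: body_system_count(s, catalog)).to_numpy()


#: Category name -> predicate over (condition_count, body_system_count).
CATEGORIES = {
    "conditions_2plus": lambda k, s: k >= 2,
    "conditions_3plus": lambda k, s: k >= 3,
    "systems_2plus": lambda k, s: s >= 2,
    "complex_multimorbidity": lambda k, s: k >= 3 and s >= 3,
}


def category_predicate(name: str, catalog: ConditionCatalog):
    """A predicate over a condition-code set implementing a named category."""
    try:
        f = CATEGORIES[name]
    except KeyError:
        raise ValueError(
            f"unknown multimorbidity category {name!r}; "
            f"choose from {sorted(CATEGORIES)}"
        ) from None

    def pred(codes) -> bool:
        return f(condition_count(codes, catalog), body_system_count(codes, catalog))

    return pred


def multimorbidity_prevalence(
    df: pd.DataFrame,
    catalog: ConditionCatalog,
    weight_set=None,
    strata=None,
) -> pd.DataFrame:
    """Prevalence of each multimorbidity category.

    With ``weight_set=None`` the estimates are encounter-level (unweighted
    proportions of sampled patients); with a weight set they are
    population-level, via the prevalence module.
    """
    from .prevalence import encounter_prevalence, population_prevalence

    rows = []
    for name in CATEGORIES:
        pred = category_predicate(name, catalog)
        if weight_set is None:
            est = encounter_prevalence(df, pred, catalog, target_name=name)
        else:
            est = population_prevalence(
                df, pred, catalog, weight_set, target_name=name
            )
        rows.append(est.as_row())
    return pd.DataFrame(rows)


def count_distribution(
    df: pd.DataFrame,
    catalog: ConditionCatalog,
    weight_set=None,
    max_count: int = 7,
    by: str = "conditions",
) -> pd.DataFrame:
    """Distribution of the number of chronic conditions (or body systems).

    Returns one row per count 0..max_count-1 plus a ``{max_count}+`` bin with
    the encounter-level (unweighted) proportion, and the population-level
    proportion when a weight set is supplied. The population column uses the
    weighted numerator C*F*G for patients in the bin (bins >= 1) and assigns
    non-attenders' mass to the 0 bin, so the column sums to 1.
    """
    if by == "conditions":
        counts = condition_counts(df, catalog)
    elif by == "systems":
        counts = body_system_counts(df, catalog)
    else:
        raise ValueError("by must be 'conditions' or 'systems'")
    binned = np.minimum(counts, max_count)
    labels = [str(i) for i in range(max_count)] + [f"{max_count}+"]
    enc = np.array([(binned == i).mean() for i in range(max_count + 1)])
    out = pd.DataFrame({"count": labels, "encounter": enc})
    if weight_set is not None:
        w = weight_set.weights
        idx = w.index.to_numpy()
        b = binned[idx]
        num = w["numerator_factor"].to_numpy()
        den = w["denominator_factor"].to_numpy()
        total = den.sum()
        pop = np.array([num[b == i].sum() / total for i in range(max_count + 1)])
        # Non-attenders (the 1-G mass) are assumed condition-free: they
        # belong to the population denominator and the 0-condition bin.
        pop[0] += (den.sum() - num.sum()) / total
        out["population"] = pop
    return out
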