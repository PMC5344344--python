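"""Encounter-level and population-level prevalence estimation.

Two distinct estimands:

* *Encounter prevalence* — the unweighted proportion of sampled patients
  with the target: prevalence among patients found at GP encounters.
* *Population prevalence* — the weighted ratio
  ``sum_i C_i F_i G_i I_i / sum_i C_i F_i`` projecting the sample onto the
  national population, where the non-attender share (1 - G) of each stratum
  is assumed condition-free.

Targets are resolvable at three levels behind one interface: a condition
code (patient has that condition), an ICPC-2 chapter letter (patient has at
least one chronic condition in the chapter — counted once per patient), or
an arbitrary predicate over the patient's condition-code set (used by the
multimorbidity categories).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .catalog import ICPC2_CHAPTERS, ConditionCatalog
from .strata import StratumReference
from .variance import PrevalenceEstimate, cluster_ratio_ci
from .weighting import WeightSet, build_weight_set

Target = "str | Callable[[frozenset], bool]"


def resolve_target(target, catalog: ConditionCatalog):
    """Normalise a target spec to ``(name, predicate over code set)``."""
    if callable(target):
        return getattr(target, "__name__", "predicate"), target
    if not isinstance(target, str):
        raise ValueError(f"target must be a string or callable, got {target!r}")
    if target in catalog:
        code = target

        def has_code(codes, _code=code):
            return _code in codes

        return target, has_code
    if target in ICPC2_CHAPTERS:
        chapter_codes = catalog.chapter_codes(target, chronic_only=True)

        def in_chapter(codes, _cc=chapter_codes):
            return not _cc.isdisjoint(codes)

        return target, in_chapter
    raise ValueError(
        f"unknown target {target!r}: not a catalog condition code or an "
        f"ICPC-2 chapter letter"
    )


def indicator(df: pd.DataFrame, target, catalog: ConditionCatalog) -> np.ndarray:
    """0/1 vector: which records meet the target."""
    _, pred = resolve_target(target, catalog)
    return df["conditions"].map(pred).to_numpy(dtype=float)


def encounter_prevalence(
    df: pd.DataFrame,
    target,
    catalog: ConditionCatalog,
    level: float = 0.95,
    target_name: str | None = None,
) -> PrevalenceEstimate:
    """Unweighted prevalence among sampled patients, cluster-design CI.

    All validated records are included, whether or not they have an
    assignable age-sex stratum.
    """
    name, _ = resolve_target(target, catalog)
    ind = indicator(df, target, catalog)
    ones = np.ones(len(df))
    est, lo, hi, g = cluster_ratio_ci(ind, ones, df["gp_id"].to_numpy(), level)
    return PrevalenceEstimate(
        target=target_name or name,
        method="encounter",
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        n=len(df),
        n_clusters=g,
    )


def population_prevalence(
    df: pd.DataFrame,
    target,
    catalog: ConditionCatalog,
    weight_set: WeightSet,
    level: float = 0.95,
    target_name: str | None = None,
) -> PrevalenceEstimate:
    """National prevalence: sum(C*F*G*I) / sum(C*F) with cluster CI.

    Restricted to the records in the weight set (patients with an
    assignable stratum)."""
    name, _ = resolve_target(target, catalog)
    w = weight_set.weights
    sub = df.loc[w.index]
    ind = indicator(sub, target, catalog)
    num = w["numerator_factor"].to_numpy() * ind
    den = w["denominator_factor"].to_numpy()
    est, lo, hi, g = cluster_ratio_ci(num, den, sub["gp_id"].to_numpy(), level)
    return PrevalenceEstimate(
        target=target_name or name,
        method=f"population_{weight_set.method}",
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        n=len(sub),
        n_clusters=g,
    )


def estimates_table(estimates: Iterable[PrevalenceEstimate]) -> pd.DataFrame:
    """Tidy table, one row per (target, method)."""
    return pd.DataFrame([e.as_row() for e in estimates])


def compare_methods(
    df: pd.DataFrame,
    targets,
    strata: StratumReference,
    catalog: ConditionCatalog,
    level: float = 0.95,
) -> pd.DataFrame:
    """Old-method vs new-method national estimates, per target.

    Returns one row per target with both estimates and CIs, the relative
    difference (new - old)/old, and whether the two CIs are disjoint (the
    conservative non-overlap significance rule).
    """
    from .variance import significant_difference

    ws_old = build_weight_set(df, strata, "old")
    ws_new = build_weight_set(df, strata, "new")
    rows = []
    for t in targets:
        name, _ = resolve_target(t, catalog)
        e_old = population_prevalence(df, t, catalog, ws_old, level)
        e_new = population_prevalence(df, t, catalog, ws_new, level)
        rel = (e_new.estimate - e_old.estimate) / e_old.estimate if e_old.estimate else np.nan
        rows.append(
            {
                "target": name,
                "old_estimate": e_old.estimate,
                "old_ci_low": e_old.ci_low,
                "old_ci_high": e_old.ci_high,
                "new_estimate": e_new.estimate,
                "new_ci_low": e_new.ci_low,
                "new_ci_high": e_new.ci_high,
                "relative_difference": rel,
                "significant": significant_difference(e_old, e_new),
            }
        )
    return pd.DataFrame(rows)
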