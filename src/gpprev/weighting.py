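"""Attendance and post-stratification weights for encounter samples.

Patients are sampled at GP encounters, so the chance of entering the sample
is proportional to how often they attend (length-biased sampling). The
weighting removes that bias and projects the sample onto the national
population:

``A``
    the patient's reported GP visits in the past 12 months (>= 1).
``B``
    the adjusted mean visit count for the whole sample — the harmonic mean
    of the A values, i.e. the average annual attendance of people who saw a
    GP at least once. (Under sampling proportional to visits, the sample
    mean of 1/A estimates 1/E[A] among attenders.)
``C = B/A``
    the attendance weight: high attenders weighted down, low attenders up.
    The previous ("old") method has no attendance information and uses C = 1.
``E``
    the (C-weighted) share of the sample in each age-sex stratum.
``F = D/E``
    the national (post-stratification) weight, D being the stratum's share
    of the national population.
``G``
    the proportion of the stratum that saw a GP at least once that year.
    Non-attenders are assumed to have no diagnosed chronic conditions, so G
    enters the prevalence *numerator* only: each patient contributes
    ``C*F*G`` to the numerator and ``C*F`` to the denominator.

All internal arithmetic is at full precision; 2-decimal rounding happens
only in the display helper :func:`table1_worked_example`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .strata import StratumReference


class WeightingError(ValueError):
    pass


def adjusted_mean_visits(visits) -> float:
    """Adjusted mean visit count B: the harmonic mean n / sum(1/A_i).

    B is the value such that the attendance-weighted (weights proportional
    to 1/A) mean of A equals B; it estimates the average attendance of
    people who visited at least once, undoing the sample's length bias.
    """
    a = np.asarray(visits, dtype=float)
    if a.size == 0:
        raise WeightingError("cannot compute adjusted mean visits of an empty sample")
    if np.isnan(a).any() or (a <= 0).any():
        raise WeightingError("all visit counts must be positive and non-missing")
    return float(a.size / np.sum(1.0 / a))


def attendance_weight(A, B: float, method: str):
    """C = B/A under the new method; C = 1 under the old method."""
    if method not in ("old", "new"):
        raise ValueError(f"method must be 'old' or 'new', got {method!r}")
    a = np.asarray(A, dtype=float)
    if (a <= 0).any() or np.isnan(a).any():
        raise WeightingError("visit counts A must be positive")
    if method == "old":
        return np.ones_like(a) if a.shape else 1.0
    if B <= 0:
        raise WeightingError("B must be positive")
    c = B / a
    return c if a.shape else float(c)

def stratum_shares(C, stratum_ids, n_strata: int) -> pd.Series:
    """E_s: the C-weighted share of the sample in each stratum.

    Under the old method all C = 1 and E is the raw sample share. Shares sum
    to 1 by construction; strata with no sample mass get E = 0.
    """
    c = np.asarray(C, dtype=float)
    ids = np.asarray(stratum_ids, dtype=int)
    if (ids < 0).any():
        raise WeightingError("every record must be assigned a stratum")
    total = c.sum()
    if total <= 0:
        raise WeightingError("total weight must be positive")
    e = np.bincount(ids, weights=c, minlength=n_strata) / total
    return pd.Series(e, index=pd.RangeIndex(n_strata), name="E")


def national_weight(D, E):
    """F = D/E, the post-stratification weight. E = 0 with D > 0 is an error."""
    d = np.asarray(D, dtype=float)
    e = np.asarray(E, dtype=float)
    bad = (e <= 0) & (d > 0)
    if bad.any():
        raise WeightingError(
            f"strata {np.where(bad)[0].tolist()} have population share but no "
            f"sample mass; drop or merge them before weighting"
        )
    f = np.divide(d, e, out=np.zeros_like(d), where=e > 0)
    return f if f.shape else float(f)


def final_factors(C, F, G):
    """(numerator C*F*G, denominator C*F).

    The non-attender adjustment G multiplies the numerator only:
    non-attenders are assumed condition-free but remain in the denominator
    population.
    """
    c = np.asarray(C, dtype=float)
    f = np.asarray(F, dtype=float)
    g = np.asarray(G, dtype=float)
    if (c <= 0).any() or (f <= 0).any():
        raise WeightingError("C and F must be strictly positive")
    if ((g <= 0) | (g > 1)).any():
        raise WeightingError("G must lie in (0, 1]")
    den = c * f
    return den * g, den


@dataclass
class WeightSet:
    """Per-patient weights plus the sample constants behind them.

    ``weights`` is indexed like the records it was built from (restricted to
    patients with an assignable stratum) with columns ``stratum, C, F, G,
    numerator_factor, denominator_factor``. ``stratum_table`` records D, E,
    F, G per stratum for audit.
    """

    method: str
    b_constant: float
    weights: pd.DataFrame
    stratum_table: pd.DataFrame
    uncovered_population_share: float = 0.0

    def __post_init__(self) -> None:
        w = self.weights
        if (w["numerator_factor"] > w["denominator_factor"] + 1e-12).any():
            raise WeightingError("numerator factor exceeded denominator factor (G > 1?)")
        for col in ("C", "F", "numerator_factor", "denominator_factor"):
            v = w[col].to_numpy()
            if not np.isfinite(v).all() or (v <= 0).any():
                raise WeightingError(f"{col} must be strictly positive and finite")
        if self.method == "old" and not np.allclose(w["C"], 1.0):
            raise WeightingError("old-method attendance weights must all be 1")


def build_weight_set(
    df: pd.DataFrame,
    strata: StratumReference,
    method: str,
    b: float | None = None,
) -> WeightSet:
    """Compose B -> C -> E -> F -> final factors for a record frame.

    Records without an assignable stratum (missing or out-of-range age/sex)
    are excluded from the weight set; callers keep them for encounter-level
    estimates. Strata with population share but no sampled patients are
    dropped with their share reported as ``uncovered_population_share``, and
    D is renormalised over the covered strata.

    ``b`` overrides the computed adjusted-mean-visits constant (useful for
    checking that prevalence is invariant to the scale of B).
    """
    visits = df["reported_visits"].to_numpy(dtype=float)
    if np.isnan(visits).any():
        raise WeightingError(
            "records contain missing visit counts; run imputation first"
        )
    ids = strata.assign_many(df["age"].to_numpy(), df["sex"].to_numpy())
    keep = ids >= 0
    if not keep.any():
        raise WeightingError("no record could be assigned to a stratum")

    b_const = adjusted_mean_visits(visits) if b is None else float(b)
    sub = df.loc[keep]
    sub_ids = ids[keep]
    C = np.asarray(attendance_weight(sub["reported_visits"].to_numpy(), b_const, method))

    n_strata = strata.n_strata
    E = stratum_shares(C, sub_ids, n_strata)
    D = strata.population_share().to_numpy(dtype=float).copy()
    covered = E.to_numpy() > 0
    uncovered = float(D[~covered].sum())
    if uncovered > 0:
        D = np.where(covered, D, 0.0)
        D = D / D.sum()
    F_strata = np.asarray(national_weight(D, E.to_numpy()))
    G_strata = strata.attender_share().to_numpy(dtype=float)

    F = F_strata[sub_ids]
    G = G_strata[sub_ids]
    num, den = final_factors(C, F, G)

    weights = pd.DataFrame(
        {
            "stratum": sub_ids,
            "C": C,
            "F": F,
            "G": G,
            "numerator_factor": num,
            "denominator_factor": den,
        },
        index=sub.index,
    )
    stratum_table = pd.DataFrame(
        {
            "population_share": D,
            "sample_share_E": E.to_numpy(),
            "national_weight_F": F_strata,
            "attender_share_G": G_strata,
        }
    )
    return WeightSet(
        method=method,
        b_constant=b_const,
        weights=weights,
        stratum_table=stratum_table,
        uncovered_population_share=uncovered,
    )


def _round2(x: float) -> float:
    """Round half up to 2 decimals (display convention)."""
    return math.floor(x * 100 + 0.5) / 100


def table1_worked_example(
    A: float | None, B: float, D: float, E: float, G: float, method: str
) -> dict[str, float]:
    """The worked weighting example for one patient, at display precision.

    Inputs are on their natural scales (D, E, G as proportions). The derived
    cells C, F, numerator C*F*G and denominator C*F are rounded to 2
    decimals, and the products are composed from the *rounded* C and F —
    the convention under which the printed example tables are internally
    consistent.
    """
    if method == "new":
        if A is None:
            raise ValueError("the new method needs the patient's visit count A")
        C = _round2(attendance_weight(float(A), B, "new"))
    else:
        C = 1.0
    F = _round2(float(national_weight(D, E)))
    return {
        "C": C,
        "F": F,
        "numerator": _round2(C * F * G),
        "denominator": _round2(C * F),
    }
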