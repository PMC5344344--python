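"""Age-sex strata: population shares (D) and attender proportions (G).

Post-stratification reweights the sample so its age-sex distribution matches
known population shares D; the non-attender adjustment multiplies each
condition indicator by G, the proportion of the stratum that saw a GP at
least once in the year, under the assumption that non-attenders carry no
diagnosed chronic conditions.

Age intervals are half-open ``[age_low, age_high)`` so that the bands
partition the age range unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_SEXES = ("male", "female")


class StratumError(ValueError):
    pass


@dataclass
class StratumReference:
    """Per age-sex stratum: population share D and attender proportion G.

    ``table`` has one row per stratum with columns
    ``sex, age_low, age_high, population_share, attender_share`` and a unique
    integer index (the stratum id). Population shares sum to 1 over all
    strata; within each sex the age bands form a gap-free partition.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"sex", "age_low", "age_high", "population_share", "attender_share"}
        missing = required - set(t.columns)
        if missing:
            raise StratumError(f"stratum reference missing columns {sorted(missing)}")
        if not set(t["sex"]).issubset(_SEXES):
            bad = sorted(set(t["sex"]) - set(_SEXES))
            raise StratumError(f"unknown sex values {bad}")
        if ((t["attender_share"] < 0) | (t["attender_share"] > 1)).any():
            raise StratumError("attender_share (G) must lie in [0, 1]")
        if (t["population_share"] < 0).any():
            raise StratumError("population_share (D) must be non-negative")

        total = float(t["population_share"].sum())
        if abs(total - 1.0) > 1e-6:
            raise StratumError(
                f"population shares sum to {total:.6g}, not 1 (tolerance 1e-6)"
            )
        if total != 1.0:
            t = t.assign(population_share=t["population_share"] / total)

        # Age bands must partition [min, max) within each sex, identically
        # ordered half-open intervals with no gaps or overlaps.
        for sex in sorted(set(t["sex"])):
            sub = t[t["sex"] == sex].sort_values("age_low")
            lows = sub["age_low"].to_numpy(dtype=float)
            highs = sub["age_high"].to_numpy(dtype=float)
            if (highs <= lows).any():
                raise StratumError(f"{sex}: age_high must exceed age_low")
            if not np.allclose(lows[1:], highs[:-1]):
                raise StratumError(
                    f"{sex}: age bands do not form a gap-free partition"
                )
        self.table = t.reset_index(drop=True)

    @property
    def n_strata(self) -> int:
        return len(self.table)

    def assign(self, age: float, sex: str) -> int:
        """Stratum id for a single (age, sex); raises if out of range."""
        ids = self.assign_many(np.asarray([age], dtype=float), np.asarray([sex]))
        if ids[0] < 0:
            raise StratumError(f"(age={age}, sex={sex}) matches no stratum")
        return int(ids[0])

    def assign_many(self, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        """Vectorised stratum assignment; -1 where no stratum applies
        (missing or out-of-range age/sex)."""
        age = np.asarray(age, dtype=float)
        sex = np.asarray(sex, dtype=object)
        out = np.full(len(age), -1, dtype=int)
        for s in _SEXES:
            sub = self.table[self.table["sex"] == s].sort_values("age_low")
            if sub.empty:
                continue
            edges = np.append(
                sub["age_low"].to_numpy(dtype=float),
                sub["age_high"].iloc[-1],
            )
            mask = (sex == s) & ~np.isnan(age)
            if not mask.any():
                continue
            pos = np.searchsorted(edges, age[mask], side="right") - 1
            valid = (pos >= 0) & (pos < len(sub))
            idx = np.where(mask)[0]
            out[idx[valid]] = sub.index.to_numpy()[pos[valid]]
        return out

    def population_share(self) -> pd.Series:
        return self.table["population_share"]

    def attender_share(self) -> pd.Series:
        return self.table["attender_share"]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def load_stratum_reference(path: str | Path) -> StratumReference:
    """Load a stratum reference CSV.

    Columns: ``sex, age_low, age_high, population_share, attender_share``.
    D is renormalised only if off by <= 1e-6; larger discrepancies are an
    error. Overlapping or gapped age bands and G outside [0, 1] are errors.
    """
    df = pd.read_csv(path)
    if "sex" in df.columns:
        df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    return StratumReference(df)


def five_year_bands(max_age: float = 85.0, open_upper: float = 120.0) -> list[tuple[float, float]]:
    """Default 5-year age bands [0,5), [5,10), ..., with an open-ended top band."""
    lows = np.arange(0.0, max_age, 5.0)
    bands = [(float(lo), float(lo + 5.0)) for lo in lows]
    bands.append((float(max_age), float(open_upper)))
    return bands
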