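"""Synthetic populations and encounter samples with known ground truth.

The generator emulates the statistical structure the estimator assumes:

* an age-sex structured population with stratum-specific chronic-condition
  prevalence rising with age;
* annual GP visit counts from a zero-inflated negative binomial whose rate
  is multiplied by ``visit_effect`` for every chronic condition — people
  with more conditions attend more often;
* *diagnosed* conditions require attendance: a person with zero visits in
  the year carries no diagnosed chronic conditions (diagnosis happens at the
  GP), which is exactly the assumption the non-attender adjustment G makes;
* encounter sampling of attenders with probability proportional to visit
  count (length-biased), partitioned into GP clusters of ~30 patients;
* the two observed missingness mechanisms — blank chronic-condition
  response and unrecorded visit count — at the rates seen in practice.

Ground truth (true diagnosed prevalence per target, true population shares
D and attender proportions G per stratum) is tallied directly from the
generated population, so recovery of truth by the estimation pipeline is a
checkable property, not an assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import ConditionCatalog, default_catalog
from .records import HAS, MISSING, NO, RECORD_COLUMNS
from .strata import StratumReference, five_year_bands

# Rough national age pyramid over 5-year bands 0-4 ... 80-84, 85+ (shares
# within one sex; the same shape is used for both sexes).
_AGE_BAND_SHARES = np.array(
    [6.3, 6.2, 5.9, 6.2, 6.8, 7.3, 7.2, 6.8, 6.5, 6.4, 6.2, 5.9,
     5.5, 4.7, 3.9, 2.9, 1.9, 1.4]
)
_AGE_BAND_SHARES = _AGE_BAND_SHARES / _AGE_BAND_SHARES.sum()

# (code, prevalence at age 0, prevalence at 85+, age power): prevalence for
# age a is p0 + (p1 - p0) * min(a/85, 1)^power. Chosen once to give an
# encounter-prevalence profile resembling a general-practice sample.
_DEFAULT_CONDITION_PROFILES = [
    ("hypertension", 0.002, 0.58, 2.0),
    ("osteoarthritis", 0.001, 0.50, 2.5),
    ("hyperlipidaemia", 0.002, 0.38, 2.0),
    ("depression", 0.030, 0.16, 1.0),
    ("anxiety", 0.030, 0.10, 0.8),
    ("gord", 0.010, 0.22, 1.5),
    ("diabetes_type2", 0.001, 0.22, 2.5),
    ("asthma", 0.070, 0.10, 1.0),
]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults encode a realistic general-practice sampling frame: 5-year
    age-sex strata, visit rates rising with age and multiplied by
    ``visit_effect`` (default 1.5) per chronic condition, negative-binomial
    dispersion ``visit_dispersion`` (shape parameter; ~1 gives the heavy
    right tail of attendance data), structural non-attendance
    ``zero_inflation``, clusters of ``patients_per_gp = 30`` consecutive
    patients, and missingness rates of 3.0% (condition response) and 4.1%
    (visit count).
    """

    strata: pd.DataFrame = None  # sex, age_low, age_high, population_share
    condition_prevalence: pd.DataFrame = None  # stratum x condition
    visit_base: np.ndarray = None  # per-stratum NB mean for condition-free
    visit_effect: float = 1.5
    visit_dispersion: float = 1.1
    #: probability of being a non-attender (zero visits all year); scalar or
    #: one value per stratum. Attenders draw zero-truncated NB visit counts,
    #: so G per stratum is 1 - zero_inflation.
    zero_inflation: float | np.ndarray = None
    population_size: int = 2_000_000
    n_gps: int = 1000
    patients_per_gp: int = 30
    p_missing_condition: float = 0.030
    p_missing_visits: float = 0.041
    p_missing_agesex: float = 0.0
    under_report: float = 1.0
    managed_rate: float = 0.3
    acute_rate: float = 0.4
    frailty_sd: float = 0.0  # optional shared frailty inducing comorbidity

    def __post_init__(self) -> None:
        if self.strata is None:
            self.strata = default_strata_table()
        if self.condition_prevalence is None:
            self.condition_prevalence = default_condition_prevalence(self.strata)
        if self.visit_base is None:
            self.visit_base = default_visit_base(self.strata)
        self.visit_base = np.asarray(self.visit_base, dtype=float)
        if self.zero_inflation is None:
            self.zero_inflation = default_zero_inflation(self.strata)
        self.zero_inflation = np.broadcast_to(
            np.asarray(self.zero_inflation, dtype=float), (len(self.strata),)
        ).copy()
        if ((self.zero_inflation < 0) | (self.zero_inflation > 1)).any():
            raise SimulationError("zero_inflation must lie in [0, 1]")
        for name in ("p_missing_condition", "p_missing_visits",
                     "p_missing_agesex", "managed_rate", "acute_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name}={v} must lie in [0, 1]")
        if self.visit_effect < 1:
            raise SimulationError(
                "visit_effect must be >= 1: people with more diagnosed "
                "chronic conditions attend at least as often"
            )
        if self.visit_dispersion <= 0 or self.under_report <= 0:
            raise SimulationError("visit_dispersion and under_report must be positive")
        if ((self.condition_prevalence.to_numpy() < 0)
                | (self.condition_prevalence.to_numpy() > 1)).any():
            raise SimulationError("condition prevalences must lie in [0, 1]")
        if len(self.visit_base) != len(self.strata):
            raise SimulationError("visit_base must have one entry per stratum")
        if self.n_gps < 2 or self.patients_per_gp < 1 or self.population_size < 1:
            raise SimulationError("invalid sample-size configuration")

    @property
    def n_sample(self) -> int:
        return self.n_gps * self.patients_per_gp

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def default_strata_table() -> pd.DataFrame:
    bands = five_year_bands()
    rows = []
    for j, sex in enumerate(("male", "female")):
        for i, (lo, hi) in enumerate(bands):
            # slight female excess at older ages
            sex_share = 0.5 + (0.02 * (i / len(bands))) * (1 if sex == "female" else -1)
            rows.append(
                {
                    "sex": sex,
                    "age_low": lo,
                    "age_high": hi,
                    "population_share": _AGE_BAND_SHARES[i] * sex_share,
                }
            )
    df = pd.DataFrame(rows)
    df["population_share"] /= df["population_share"].sum()
    return df


def default_condition_prevalence(strata: pd.DataFrame) -> pd.DataFrame:
    mids = (strata["age_low"] + np.minimum(strata["age_high"], 95)) / 2
    frac = np.clip(mids / 85.0, 0, 1)
    cols = {}
    for code, p0, p1, power in _DEFAULT_CONDITION_PROFILES:
        cols[code] = p0 + (p1 - p0) * frac**power
    return pd.DataFrame(cols, index=strata.index)


def default_visit_base(strata: pd.DataFrame) -> np.ndarray:
    mids = (strata["age_low"] + np.minimum(strata["age_high"], 95)) / 2
    frac = np.clip(mids.to_numpy() / 85.0, 0, 1)
    base = 1.0 + 2.8 * frac**1.5
    return base * np.where(strata["sex"].to_numpy() == "female", 1.15, 1.0)


def default_zero_inflation(strata: pd.DataFrame) -> np.ndarray:
    """Non-attender share per stratum: highest for young men, near zero for
    the very old — giving G from ~0.75 up to ~0.97."""
    mids = (strata["age_low"] + np.minimum(strata["age_high"], 95)) / 2
    frac = np.clip(mids.to_numpy() / 85.0, 0, 1)
    pi = 0.26 - 0.23 * frac**0.8
    return pi * np.where(strata["sex"].to_numpy() == "female", 0.75, 1.0)


@dataclass
class Population:
    """A generated population with its ground truth."""

    config: SimulationConfig
    frame: pd.DataFrame  # age, sex, stratum, visits
    diagnosed: np.ndarray  # persons x conditions bool matrix
    condition_names: list[str]
    truth: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.frame)


def generate_population(config: SimulationConfig, seed: int) -> Population:
    """Draw a population and tally its ground truth.

    Latent conditions are drawn independently per condition at the stratum
    prevalence (optionally correlated through a log-normal shared frailty);
    visit counts are zero-inflated negative binomial with mean
    ``visit_base * visit_effect**(latent condition count)``; *diagnosed*
    conditions are the latent conditions of people with >= 1 visit.
    """
    rng = np.random.default_rng(seed)
    strata = config.strata
    n = config.population_size
    n_strata = len(strata)

    stratum = rng.choice(n_strata, size=n, p=strata["population_share"].to_numpy())
    lo = strata["age_low"].to_numpy()[stratum]
    hi = np.minimum(strata["age_high"].to_numpy(), 95.0)[stratum]
    age = np.floor(rng.uniform(lo, hi))
    sex = strata["sex"].to_numpy()[stratum]

    prev = config.condition_prevalence.to_numpy()[stratum]  # n x c
    if config.frailty_sd > 0:
        frailty = rng.lognormal(-config.frailty_sd**2 / 2, config.frailty_sd, size=n)
        prev = np.clip(prev * frailty[:, None], 0, 1)
    latent = rng.random(prev.shape) < prev
    k = latent.sum(axis=1)

    lam = config.visit_base[stratum] * config.visit_effect ** k
    r = config.visit_dispersion
    attender = rng.random(n) >= config.zero_inflation[stratum]
    # Attenders draw zero-truncated negative binomial counts (>= 1 by
    # definition: they saw a GP that year); rejection redraw of zeros.
    visits = rng.negative_binomial(r, r / (r + lam))
    visits[~attender] = 0
    todo = attender & (visits == 0)
    while todo.any():
        visits[todo] = rng.negative_binomial(r, r / (r + lam[todo]))
        todo = attender & (visits == 0)

    diagnosed = latent & attender[:, None]

    frame = pd.DataFrame(
        {"age": age, "sex": sex, "stratum": stratum, "visits": visits}
    )
    names = list(config.condition_prevalence.columns)

    d_true = np.bincount(stratum, minlength=n_strata) / n
    g_true = np.zeros(n_strata)
    np.divide(
        np.bincount(stratum, weights=attender.astype(float), minlength=n_strata),
        np.bincount(stratum, minlength=n_strata),
        out=g_true,
        where=np.bincount(stratum, minlength=n_strata) > 0,
    )
    truth = {
        "population_share_D": d_true.tolist(),
        "attender_share_G": g_true.tolist(),
        "prevalence": {
            name: float(diagnosed[:, i].mean()) for i, name in enumerate(names)
        },
        "attender_mean_visits": float(visits[attender].mean()),
        "overall_attender_share": float(attender.mean()),
    }
    catalog = default_catalog()
    known = [nm for nm in names if nm in catalog]
    if len(known) == len(names):
        chapters = np.array([catalog.chapter(nm) for nm in names])
        counts = diagnosed.sum(axis=1)
        uniq = sorted(set(chapters))
        sys_counts = np.zeros(n, dtype=int)
        for ch in uniq:
            sys_counts += diagnosed[:, chapters == ch].any(axis=1)
        truth["multimorbidity"] = {
            "conditions_2plus": float((counts >= 2).mean()),
            "conditions_3plus": float((counts >= 3).mean()),
            "systems_2plus": float((sys_counts >= 2).mean()),
            "complex_multimorbidity": float(
                ((counts >= 3) & (sys_counts >= 3)).mean()
            ),
        }
    return Population(
        config=config, frame=frame, diagnosed=diagnosed,
        condition_names=names, truth=truth,
    )


def reference_tables_from_truth(population: Population) -> StratumReference:
    """D_true and G_true in the exact format the estimation pipeline loads."""
    strata = population.config.strata
    table = strata[["sex", "age_low", "age_high"]].copy()
    table["population_share"] = population.truth["population_share_D"]
    table["attender_share"] = population.truth["attender_share_G"]
    return StratumReference(table)


def sample_encounters(
    population: Population, config: SimulationConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw an encounter sample: attenders with probability proportional to
    visit count, without replacement, clustered into GPs of
    ``patients_per_gp`` patients, with reporting and missingness applied."""
    config = config or population.config
    rng = np.random.default_rng(seed)
    visits = population.frame["visits"].to_numpy()
    attenders = np.where(visits >= 1)[0]
    n_sample = config.n_sample
    if n_sample > len(attenders):
        raise SimulationError(
            f"requested sample of {n_sample} exceeds the attender pool "
            f"({len(attenders)})"
        )
    # Weighted sampling without replacement (exponential-key trick):
    # the n smallest Exp(1)/w keys are a PPS-without-replacement draw.
    keys = rng.exponential(size=len(attenders)) / visits[attenders]
    chosen = attenders[np.argpartition(keys, n_sample - 1)[:n_sample]]
    chosen = rng.permutation(chosen)

    true_visits = visits[chosen].astype(float)
    reported = true_visits
    if config.under_report != 1.0:
        reported = np.maximum(1.0, np.round(true_visits * config.under_report))

    diag = population.diagnosed[chosen]
    names = np.array(population.condition_names)
    conditions = [frozenset(names[row]) for row in diag]

    managed_mask = diag & (rng.random(diag.shape) < config.managed_rate)
    acute_draw = rng.random(n_sample) < config.acute_rate
    acute_codes = np.array(["acute_urti", "acute_gastroenteritis", "acute_injury"])
    acute_pick = rng.integers(0, len(acute_codes), size=n_sample)
    managed = []
    for i in range(n_sample):
        m = set(names[managed_mask[i]])
        if acute_draw[i]:
            m.add(acute_codes[acute_pick[i]])
        managed.append(frozenset(m))

    response = np.where([len(c) > 0 for c in conditions], HAS, NO).astype(object)
    cond_missing = rng.random(n_sample) < config.p_missing_condition
    response[cond_missing] = MISSING
    conditions = [
        frozenset() if m else c for c, m in zip(conditions, cond_missing)
    ]

    reported = reported.astype(float)
    reported[rng.random(n_sample) < config.p_missing_visits] = np.nan

    age = population.frame["age"].to_numpy()[chosen].astype(float)
    sex = population.frame["sex"].to_numpy()[chosen].astype(object)
    if config.p_missing_agesex > 0:
        age[rng.random(n_sample) < config.p_missing_agesex] = np.nan
        sex[rng.random(n_sample) < config.p_missing_agesex] = None

    gp = np.arange(n_sample) // config.patients_per_gp
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in chosen],
            "gp_id": [f"gp{g:04d}" for g in gp],
            "age": age,
            "sex": sex,
            "reported_visits": reported,
            "condition_response": response,
            "conditions": conditions,
            "encounter_managed": managed,
            "visits_imputed": False,
        },
        columns=RECORD_COLUMNS,
    )
    return df


def simulate_bundle(
    config: SimulationConfig, seed: int, outdir: str | Path
) -> dict[str, Path]:
    """Generate a population + sample and write records/reference/truth files."""
    from .records import write_records

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop = generate_population(config, seed)
    records = sample_encounters(pop, config, seed=seed + 1)
    ref = reference_tables_from_truth(pop)

    paths = {
        "records": outdir / "records.csv",
        "reference": outdir / "reference.csv",
        "truth": outdir / "truth.json",
    }
    write_records(records, paths["records"])
    ref.to_csv(paths["reference"])
    paths["truth"].write_text(json.dumps(pop.truth, indent=2) + "\n")
    return paths
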