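#!/usr/bin/env python
"""Multimorbidity at encounters vs in the population.

Tabulates the prevalence of >=2 and >=3 chronic conditions, >=2 affected
body systems, and complex multimorbidity (>=3 conditions across >=3 ICPC-2
chapters), unweighted (encounter) and weighted (population, new method),
plus the full distribution of condition counts. Because frequent attenders
carry more conditions, every multimorbidity measure is markedly lower in
the population than at encounters. Writes results/multimorbidity/.
"""

from pathlib import Path

from gpprev import (
    build_weight_set,
    count_distribution,
    default_catalog,
    impute_all,
    load_records,
    load_stratum_reference,
    multimorbidity_prevalence,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results" / "multimorbidity"


def main() -> None:
    catalog = default_catalog()
    records = load_records(SIM / "records.csv", catalog)
    reference = load_stratum_reference(SIM / "reference.csv")
    df, _ = impute_all(records, catalog)
    ws = build_weight_set(df, reference, "new")

    cats = multimorbidity_prevalence(df, catalog).merge(
        multimorbidity_prevalence(df, catalog, weight_set=ws),
        on="target", suffixes=("_encounter", "_population"),
    )
    dist = count_distribution(df, catalog, weight_set=ws)

    OUT.mkdir(parents=True, exist_ok=True)
    cats.to_csv(OUT / "categories.csv", index=False)
    dist.to_csv(OUT / "condition_count_distribution.csv", index=False)

    print("category                     encounter    population (new)")
    for row in cats.itertuples(index=False):
        print(f"{row.target:28s} {100 * row.estimate_encounter:5.1f}%"
              f"        {100 * row.estimate_population:5.1f}%")
    print("\ncondition-count distribution:")
    for row in dist.itertuples(index=False):
        print(f"  {row.count:>2s} conditions: encounter {100 * row.encounter:5.1f}%  "
              f"population {100 * row.population:5.1f}%")
    print(f"\ntables written to {OUT}")


if __name__ == "__main__":
    main()
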