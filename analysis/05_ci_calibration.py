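#!/usr/bin/env python
"""Check the cluster-design CIs: empirical coverage and bootstrap agreement.

Resamples 500 encounter studies (100 GP clusters each) from two fixed
populations and measures how often the linearised 95% CI covers the true
prevalence, then compares the linearised CI width with a 2,000-rep
GP-resampling bootstrap on one sample. Writes results/ci_calibration.json.
"""

import json
from pathlib import Path

from gpprev import (
    SimulationConfig,
    build_weight_set,
    cluster_bootstrap_ci,
    cluster_ratio_ci,
    default_catalog,
    generate_population,
    impute_all,
    population_prevalence,
    reference_tables_from_truth,
    sample_encounters,
)
from gpprev.prevalence import indicator

SEED = 20260929
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    catalog = default_catalog()
    cfg = SimulationConfig(n_gps=100, population_size=400_000)
    cover = total = 0
    for pop_k in range(2):
        pop = generate_population(cfg, SEED + pop_k)
        ref = reference_tables_from_truth(pop)
        truth = pop.truth["prevalence"]["hypertension"]
        for r in range(250):
            rec = sample_encounters(pop, cfg, seed=SEED + 100 + 250 * pop_k + r)
            df, _ = impute_all(rec, catalog)
            ws = build_weight_set(df, ref, "new")
            e = population_prevalence(df, "hypertension", catalog, ws)
            cover += e.ci_low <= truth <= e.ci_high
            total += 1
    coverage = cover / total

    pop = generate_population(cfg, SEED)
    ref = reference_tables_from_truth(pop)
    rec = sample_encounters(pop, cfg, seed=SEED + 999)
    df, _ = impute_all(rec, catalog)
    ws = build_weight_set(df, ref, "new")
    sub = df.loc[ws.weights.index]
    num = ws.weights["numerator_factor"].to_numpy() * indicator(
        sub, "hypertension", catalog
    )
    den = ws.weights["denominator_factor"].to_numpy()
    clusters = sub["gp_id"].to_numpy()
    _, lo, hi, _ = cluster_ratio_ci(num, den, clusters)
    _, blo, bhi, _ = cluster_bootstrap_ci(num, den, clusters, reps=2000,
                                          seed=SEED)
    out = {
        "coverage_95ci": coverage,
        "n_replicates": total,
        "linearised_width": hi - lo,
        "bootstrap_width": bhi - blo,
        "relative_width_difference": abs((bhi - blo) - (hi - lo)) / (hi - lo),
    }
    path = ROOT / "results" / "ci_calibration.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=2) + "\n")
    print(f"empirical coverage of the 95% CI: {100 * coverage:.1f}% "
          f"({total} replicates)")
    print(f"linearised width {hi - lo:.4f} vs bootstrap width {bhi - blo:.4f} "
          f"({100 * out['relative_width_difference']:.1f}% apart)")
    print(f"written to {path}")


if __name__ == "__main__":
    main()
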