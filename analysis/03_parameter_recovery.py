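#!/usr/bin/env python
"""Parameter recovery on simulated cohorts.

Simulates cohorts with a planted per-allele enrichment odds ratio for
known-mutation cases and a planted carrier AAO shift, then checks that the
allele-sum logistic model and the AAO regression recover them.

Finding: across seeded replicates the allele-sum model recovers the planted
OR without systematic bias (Wald CI coverage ~ 95%), and the AAO regression
recovers a -2.1 y carrier shift to within a few tenths of a year.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from oligopd.aao_model import aao_regression
from oligopd.burden_stats import allele_burden
from oligopd.classify import classify_cohort
from oligopd.panel import default_panel
from oligopd.synth_cohort import PrimaryGenePlan, SimulationConfig, simulate
from oligopd.variant_filter import filter_variants

RESULTS = Path(__file__).resolve().parent.parent / "results"


def seeds(seed, stream, n):
    return [int(s % 2**31)
            for s in np.random.SeedSequence([seed, stream]).generate_state(n)]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--reps", type=int, default=50)
    args = parser.parse_args()
    panel = default_panel()

    true_or, n_side = 1.70, 10_000
    ests, covered = [], 0
    for s in seeds(args.seed, 1, args.reps):
        cfg = SimulationConfig(
            seed=s, n_cases=n_side, n_controls=n_side,
            primary_plan={"LRRK2": PrimaryGenePlan(n_dominant=n_side)},
            enrichment_or=true_or,
        )
        res = simulate(cfg)
        filtered, _ = filter_variants(res.cohort, panel)
        cls = classify_cohort(filtered, panel)
        r = allele_burden(cls, filtered.samples, "known_mutation_pd", "control")
        ests.append(r.or_adj)
        covered += r.ci95[0] <= true_or <= r.ci95[1]
    print(f"planted per-allele OR {true_or}: mean estimate "
          f"{np.mean(ests):.3f} over {args.reps} reps, "
          f"CI coverage {100 * covered / args.reps:.0f}%")

    true_shift, shifts = -2.1, []
    for s in seeds(args.seed, 2, args.reps):
        cfg = SimulationConfig(
            seed=s, n_cases=5_000, n_controls=100, primary_plan={},
            aao_shift_mendelian=true_shift, aao_shift_gba=0.0,
        )
        res = simulate(cfg)
        filtered, _ = filter_variants(res.cohort, panel)
        cls = classify_cohort(filtered, panel)
        a = aao_regression(cls, filtered.samples, "no_known_mutation_pd", "mendelian")
        shifts.append(a.coeff)
    print(f"planted AAO shift {true_shift} y: mean estimate {np.mean(shifts):.2f} y")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "parameter_recovery.json").write_text(json.dumps({
        "enrichment_or": {"true": true_or, "mean_estimate": float(np.mean(ests)),
                          "ci_coverage": covered / args.reps, "reps": args.reps,
                          "n_per_arm": n_side},
        "aao_shift_years": {"true": true_shift,
                            "mean_estimate": float(np.mean(shifts)),
                            "reps": args.reps, "n_cases": 5000},
        "seed": args.seed,
    }, indent=2) + "\n")
    print(f"written to {RESULTS / 'parameter_recovery.json'}")


if __name__ == "__main__":
    main()
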