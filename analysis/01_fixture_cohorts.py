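#!/usr/bin/env python
"""Build the published-count cohorts and run the full pipeline over them.

Reconstructs the chip (NeuroX-style) and exome cohorts from their printed
carrier-count distributions and primary-mutation composition, then runs
read -> filter -> classify -> burden -> AAO end-to-end, writing the
carrier-distribution, burden and AAO tables under results/<platform>/.

Finding: the known-mutation groups carry additional rare Mendelian-gene
variants more often than controls (16.9% vs 9.2% on the chip, 33.3% vs
15.4% in exomes; unadjusted carrier OR ~ 2.0 on the chip), and carriers
have earlier onset (-5.9 y chip, -4.0 y exome in known-mutation cases).
"""

from pathlib import Path

from oligopd.burden_stats import carrier_distribution
from oligopd.pipeline import RunConfig, run_pipeline
from oligopd.plans import exome_plan, neurox_plan
from oligopd.synth_cohort import build_fixture, write_cohort_inputs

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for plan_fn in (neurox_plan, exome_plan):
        plan = plan_fn()
        cohort = build_fixture(plan)
        inputs = write_cohort_inputs(cohort, RESULTS / plan.platform / "inputs")
        config = RunConfig(
            vcf=str(inputs["vcf"]),
            annotation=str(inputs["annotation"]),
            phenotypes=str(inputs["phenotypes"]),
            cnvs=str(inputs["cnvs"]),
            out_dir=str(RESULTS / plan.platform),
        )
        bundle = run_pipeline(config)
        print(f"== {plan.platform}: {cohort.n_samples} samples, "
              f"{bundle['filter_report'].n_variants_out} variants retained ==")
        for group in ("known_mutation_pd", "no_known_mutation_pd", "control"):
            d = carrier_distribution(bundle["classifications"], group, "mendelian")
            carriers = sum(n for k, n in d.counts.items() if k >= 1)
            print(f"  {group:22s} {carriers}/{d.n} "
                  f"({100 * carriers / d.n:.1f}%) carry additional variants")
        for r in bundle["burden"]:
            if r.model == "carrier_logistic" and r.or_unadjusted is not None:
                print(f"  {r.label}: unadjusted OR {r.or_unadjusted:.2f}")
    print(f"tables written under {RESULTS}/")


if __name__ == "__main__":
    main()
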