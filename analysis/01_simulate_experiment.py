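#!/usr/bin/env python
"""Simulate the seven-sample spray experiment under two scenarios.

Generates FASTQ read sets for (a) the degradation-only scenario the
study observed — sprayed dsRNA decays on the leaf surface, no DCL
products, no transitivity — and (b) a genuine-RNAi positive scenario
(30% DCL products, 5% transitive reads in the reporter line). FASTQ
output is bulky and goes to scratch/; the sample summary goes to
results/.

Run from the repository root: python analysis/01_simulate_experiment.py
"""

from pathlib import Path

import pandas as pd

from srna_signature.simulate import (
    TRIGGER_MIDGFP,
    default_design,
    default_reference,
    negative_scenario_configs,
    positive_scenario_configs,
    simulate_experiment,
)

N_READS = 20_000  # desk-scale library size per sample
SEED = 0

SCRATCH = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    ref = default_reference()
    design = default_design()
    rows = []
    for scenario, configs in (
        ("negative", negative_scenario_configs(N_READS)),
        ("positive", positive_scenario_configs(N_READS)),
    ):
        outdir = SCRATCH / scenario
        paths = simulate_experiment(design, configs, ref, TRIGGER_MIDGFP, outdir, SEED)
        for spec in design.samples:
            rows.append(
                {
                    "scenario": scenario,
                    "sample": spec.sample_id,
                    "condition": spec.condition,
                    "n_reads": N_READS,
                    "fastq": str(paths[spec.sample_id]),
                }
            )
        print(f"{scenario}: wrote {len(paths)} FASTQ files under {outdir}/")
    RESULTS.mkdir(exist_ok=True)
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "simulation_summary.tsv", sep="\t", index=False)
    print(f"sample sheet -> {RESULTS / 'simulation_summary.tsv'}")


if __name__ == "__main__":
    main()
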