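#!/usr/bin/env python
"""Count the simulated FASTQ reads into size-class tables.

For every sample of both scenarios: length-filter (17-29 nt), map
exactly to the synthetic target reference, and count uniquely mapped
reads per (region, strand, length). Tables land in results/counts/;
a combined per-length summary in results/size_class_counts.tsv.

Requires the FASTQ output of 01_simulate_experiment.py.
"""

from pathlib import Path

import pandas as pd

from srna_signature.readproc import (
    ReferenceIndex,
    count_by_size_and_region,
    filter_by_length,
)
from srna_signature.reads import read_fastq
from srna_signature.sequences import derive_flanks
from srna_signature.simulate import TRIGGER_MIDGFP, default_reference

RESULTS = Path("results")
WINDOW = (17, 29)


def main() -> None:
    sheet_path = RESULTS / "simulation_summary.tsv"
    if not sheet_path.exists():
        raise SystemExit("run analysis/01_simulate_experiment.py first")
    sheet = pd.read_csv(sheet_path, sep="\t")
    ref = default_reference()
    regions = [TRIGGER_MIDGFP] + derive_flanks(TRIGGER_MIDGFP, ref.length)
    index = ReferenceIndex(ref, WINDOW)
    summary_rows = []
    for row in sheet.itertuples():
        reads = read_fastq(row.fastq)
        reads, _discards = filter_by_length(reads, *WINDOW)
        table = count_by_size_and_region(
            reads, ref, regions,
            count_range=WINDOW, length_window=WINDOW,
            sample_id=row.sample, condition=row.condition,
            total_reads=row.n_reads, index=index,
        )
        outdir = RESULTS / "counts" / row.scenario
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_tsv(outdir / f"{row.sample}.tsv")
        for length, count in table.length_counts().items():
            summary_rows.append(
                {
                    "scenario": row.scenario,
                    "sample": row.sample,
                    "condition": row.condition,
                    "length": length,
                    "target_mapped_reads": count,
                }
            )
        print(
            f"{row.scenario}/{row.sample}: {table.mapped_reads} mapped, "
            f"{table.ambiguous} ambiguous, {table.mir159_reads} miR159-decoy"
        )
    pd.DataFrame(summary_rows).to_csv(
        RESULTS / "size_class_counts.tsv", sep="\t", index=False
    )
    print(f"per-length summary -> {RESULTS / 'size_class_counts.tsv'}")


if __name__ == "__main__":
    main()
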