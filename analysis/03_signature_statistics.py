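#!/usr/bin/env python
"""Run the statistical battery and classify each data set.

Three analyses:

1. The embedded seven-sample count fixture (the published experiment's
   ROI counts): per-length Student t, water-normalized ANOVA in both
   orientations, decay fits, transitivity, and the verdict.
2. The simulated degradation-only scenario (from 02) — should reproduce
   the published outcome: DEGRADATION_ONLY.
3. The simulated positive scenario — should be flagged DCL_PROCESSED.

Reports go to results/ as JSON; figure-style TSVs for the fixture too.
"""

import json
from pathlib import Path

from srna_signature.pipeline import analyze_tables, load_table1_fixture
from srna_signature.readproc import SizeClassTable

RESULTS = Path("results")


def analyze_and_report(tables, label: str):
    report = analyze_tables(tables)
    out = RESULTS / f"{label}_report.json"
    out.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    print(f"{label}: {report.classification}")
    for note in report.notes:
        print(f"  - {note}")
    return report


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    fixture = load_table1_fixture()
    report = analyze_and_report(fixture, "table1")
    report.enrichment_raw.to_frame().to_csv(
        RESULTS / "table1_fig2a_raw.tsv", sep="\t", index=False
    )
    rows = [
        {
            "orientation": rec["orientation"],
            "length": rec.get("length"),
            "condition": rec.get("condition"),
            "f_statistic": rec["f_statistic"],
            "p_value": rec["p_value"],
            "letters": json.dumps(rec["letters"]),
        }
        for rec in report.enrichment_normalized
    ]
    import pandas as pd

    pd.DataFrame(rows).to_csv(
        RESULTS / "table1_fig2b_normalized.tsv", sep="\t", index=False
    )

    for scenario in ("negative", "positive"):
        counts_dir = RESULTS / "counts" / scenario
        if not counts_dir.exists():
            print(f"{scenario}: no counts found, run 01 and 02 first — skipped")
            continue
        tables = {
            (t := SizeClassTable.from_tsv(path)).sample_id: t
            for path in sorted(counts_dir.glob("*.tsv"))
        }
        analyze_and_report(tables, f"simulated_{scenario}")


if __name__ == "__main__":
    main()
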