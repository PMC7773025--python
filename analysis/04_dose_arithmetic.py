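#!/usr/bin/env python
"""Dose and effective-molarity arithmetic of the sprayed RNA species.

Tabulates the molarity of every sprayed dose, the phased siRNA yield of
each trigger duplex, and the molar / siRNA-equivalent ratios of the
highest dsRNA doses against the low-concentration positive-control
siRNA (whose molarity is conventionally rounded to 0.1 uM before
ratios are taken). Output: results/dose_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from srna_signature.dose import (
    DoseSpec,
    effective_molarity_ratio,
    molar_result,
    sum_yields,
)

RESULTS = Path("results")

DOSES = [
    DoseSpec(10, 139, "duplex", "dsRNA-midGFP 10 ng/ul"),
    DoseSpec(20, 139, "duplex", "dsRNA-midGFP 20 ng/ul"),
    DoseSpec(200, 139, "duplex", "dsRNA-midGFP 200 ng/ul"),
    DoseSpec(240, 139, "duplex", "dsRNA-midGFP 240 ng/ul"),
    DoseSpec(24, 322, "duplex", "dsRNA-5'GFP 24 ng/ul"),
    DoseSpec(48, 322, "duplex", "dsRNA-5'GFP 48 ng/ul"),
    DoseSpec(240, 322, "duplex", "dsRNA-5'GFP 240 ng/ul"),
    DoseSpec(1.4, 22, "duplex", "siRNA#164 1.4 ng/ul"),
    DoseSpec(14, 22, "duplex", "siRNA#164 14 ng/ul"),
]
REFERENCE = DoseSpec(1.4, 22, "duplex", "siRNA#164 low")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for dose in DOSES:
        result = molar_result(dose)
        molar_ratio, effective_ratio = effective_molarity_ratio(
            dose, REFERENCE, reference_molarity_override=0.1
        )
        rows.append(
            {
                "label": dose.label,
                "conc_ng_ul": dose.concentration,
                "length": dose.length,
                "molarity_uM": round(result.molarity, 3),
                "sirna_yield": result.sirna_yield,
                "effective_molarity_uM": round(result.effective_molarity, 3),
                "molar_ratio_vs_low_sirna": round(molar_ratio, 1),
                "effective_ratio_vs_low_sirna": round(effective_ratio, 1),
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "dose_summary.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    print(
        f"\nsynthesis totals: midGFP "
        f"{sum_yields([33.4, 36.7, 36.1, 35.3, 99.1, 117.8])} ug in 6 reactions, "
        f"5'GFP {sum_yields([80.6, 30.7, 115.7])} ug in 3 reactions"
    )


if __name__ == "__main__":
    main()
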