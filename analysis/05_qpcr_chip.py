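"""Delta-Ct qPCR and percent-input ChIP-qPCR on synthetic plates.

Builds small synthetic Ct tables shaped like the study's validation
experiments — FRO2/IRT1 expression relative to ACT2 with wild type +Fe
as calibrator, and H3K27me3 ChIP at FIT/FRO2 amplicons normalized to
10% of input with clf +Fe as calibrator — and runs both calculators.
The Ct values are constructed, not measured; they exercise the
arithmetic, not the biology.
"""

from pathlib import Path

import pandas as pd

from irondelta import relative_enrichment, relative_expression

OUT = Path(__file__).resolve().parents[1] / "results"


def synthetic_plate() -> pd.DataFrame:
    # ACT2 constant at 20 cycles; target Cts chosen so -Fe induction and
    # the wt-vs-clf difference are visible after the delta-Ct transform
    rows = []
    targets = {"FRO2": {"WT_plusFe": 28.0, "WT_minusFe": 24.2, "clf_plusFe": 27.6, "clf_minusFe": 22.3},
               "IRT1": {"WT_plusFe": 27.0, "WT_minusFe": 23.5, "clf_plusFe": 26.8, "clf_minusFe": 22.3}}
    for sample in ("WT_plusFe", "WT_minusFe", "clf_plusFe", "clf_minusFe"):
        rows.append({"sample_id": sample, "target": "ACT2", "ct": 20.0, "is_reference": True})
        for t, cts in targets.items():
            rows.append({"sample_id": sample, "target": t, "ct": cts[sample], "is_reference": False})
    return pd.DataFrame(rows)


def synthetic_chip() -> pd.DataFrame:
    # H3K27me3 stronger at FIT/FRO2 chromatin in wild type than in clf
    rows = []
    ip_ct = {("clf_plusFe", "FIT-a"): 27.0, ("clf_plusFe", "FRO2-b"): 27.5,
             ("WT_plusFe", "FIT-a"): 24.8, ("WT_plusFe", "FRO2-b"): 25.1,
             ("WT_minusFe", "FIT-a"): 25.6, ("WT_minusFe", "FRO2-b"): 25.9}
    for (sample, region), ct in ip_ct.items():
        rows.append({"sample_id": sample, "region": region, "antibody": "H3K27me3",
                     "ct_ip": ct, "ct_input": 22.0, "input_fraction": 0.10})
    return pd.DataFrame(rows)


def main() -> None:
    plate = synthetic_plate()
    plate.to_csv(OUT / "qpcr_plate.synthetic.csv", index=False)
    rel = relative_expression(plate, calibrator_sample="WT_plusFe")
    rel.to_csv(OUT / "qpcr_relative_expression.tsv", sep="\t", index=False)
    for _, r in rel.iterrows():
        print(f"{r['sample_id']:>12} {r['target']}: {r['rel_expression']:.1f}x WT +Fe")

    chip = synthetic_chip()
    chip.to_csv(OUT / "chip_table.synthetic.csv", index=False)
    enr = relative_enrichment(chip, calibrator_sample="clf_plusFe")
    enr.to_csv(OUT / "chip_relative_enrichment.tsv", sep="\t", index=False)
    for _, r in enr.iterrows():
        print(
            f"{r['sample_id']:>12} {r['region']}: {r['enrichment']:.2f}% of input, "
            f"{r['rel_enrichment']:.1f}x clf +Fe"
        )


if __name__ == "__main__":
    main()
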