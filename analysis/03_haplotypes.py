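#!/usr/bin/env python
"""DPA1~DPB1 and DQA1~DQB1 haplotype frequencies by two-locus EM and
per-haplotype chi-squared association on EM-expected chromosome counts.

Reads results/cohort.csv; writes results/haplotype_association.tsv; prints
the protective DPA1*01:03~DPB1*04:01 row and the opposing-direction
haplotypes carrying DPA1*01:03.
"""
from pathlib import Path

from hlapocket.cohort import read_cohort
from hlapocket.pipeline import haplotype_stage, write_tsv

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_cohort(RESULTS / "cohort.csv")
    rows, _est = haplotype_stage(table)
    write_tsv(rows, ["pair", "scope", "haplotype", "freq", "case_count",
                     "control_count", "or", "ci_low", "ci_high", "p",
                     "family_m", "threshold", "flags"],
              RESULTS / "haplotype_association.tsv")

    print("DPA1~DPB1 haplotypes, full cohort:")
    for row in rows:
        if row["pair"] != "DPA1~DPB1" or row["scope"] != "all":
            continue
        if row["haplotype"].startswith("DPA1*01:03") or \
                row["haplotype"] == "binned":
            flag = f" [{row['flags']}]" if row["flags"] else ""
            print(f"  {row['haplotype']}: OR {row['or']:.2f} "
                  f"({row['ci_low']:.2f}, {row['ci_high']:.2f}), "
                  f"p = {row['p']:.3g}{flag}")


if __name__ == "__main__":
    main()
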