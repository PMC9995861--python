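#!/usr/bin/env python
"""Allele frequencies (with 95% CIs) and additive-model logistic association
per gene and scope, with per-gene Bonferroni families — the allele-level
stage of the analysis.

Reads results/cohort.csv; writes results/frequencies.tsv and
results/allele_association.tsv; prints the headline DP rows.
"""
from pathlib import Path

from hlapocket.cohort import read_cohort
from hlapocket.pipeline import (allele_association_stage,
                                allele_frequency_stage, write_tsv)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_cohort(RESULTS / "cohort.csv")
    freq_rows, retained = allele_frequency_stage(table, 0.05)
    write_tsv(freq_rows, ["gene", "scope", "status", "allele", "n", "total",
                          "freq", "ci_low", "ci_high"],
              RESULTS / "frequencies.tsv")
    assoc_rows, _ = allele_association_stage(table, retained, 0.05)
    write_tsv(assoc_rows, ["gene", "scope", "allele", "or", "ci_low",
                           "ci_high", "p", "n", "family_m", "threshold",
                           "significant", "flags"],
              RESULTS / "allele_association.tsv")

    for gene in table.genes:
        print(f"{gene}: {len(retained[gene])} common alleles "
              f"(family threshold {0.05 / max(len(retained[gene]), 1):.4g})")
    print("\nheadline full-cohort associations:")
    for row in assoc_rows:
        if row["scope"] == "all" and row["allele"] in (
                "DPA1*01:03", "DPA1*02:01", "DPB1*04:01"):
            print(f"  {row['allele']}: OR {row['or']:.2f} "
                  f"({row['ci_low']:.2f}, {row['ci_high']:.2f}), "
                  f"p = {row['p']:.3g}")


if __name__ == "__main__":
    main()
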