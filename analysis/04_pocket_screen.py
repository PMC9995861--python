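#!/usr/bin/env python
"""The discovery stage: opposing-directionality screen over significant
alleles, derivation of candidate pocket residues from the opposing groups,
and association of the ten alpha/beta pocket residue combinations (cis
dosages via the EM phase posteriors).

Reads results/cohort.csv; writes results/screen.tsv,
results/candidate_residues.tsv and results/combo_association.tsv.
"""
from pathlib import Path

from hlapocket.cohort import read_cohort
from hlapocket.pipeline import (allele_association_stage,
                                allele_frequency_stage, combo_stage,
                                haplotype_stage, screen_stage, write_tsv)
from hlapocket.screen import DEFAULT_COMBOS

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_cohort(RESULTS / "cohort.csv")
    _, retained = allele_frequency_stage(table, 0.05)
    _, full_results = allele_association_stage(table, retained, 0.05)
    screen_rows, candidate_rows = screen_stage(full_results, 0.05)
    write_tsv(screen_rows, ["gene", "direction", "allele", "or", "p"],
              RESULTS / "screen.tsv")
    write_tsv(candidate_rows, ["gene", "chain", "position", "pockets",
                               "protective_residues", "susceptible_residues"],
              RESULTS / "candidate_residues.tsv")

    _, estimates = haplotype_stage(table)
    combo_rows = combo_stage(table, estimates, DEFAULT_COMBOS)
    write_tsv(combo_rows, ["combo", "pocket", "scope", "or", "ci_low",
                           "ci_high", "p", "n", "family_m", "threshold",
                           "significant", "flags"],
              RESULTS / "combo_association.tsv")

    print("candidate pocket residues from opposing allele groups:")
    for row in candidate_rows:
        print(f"  {row['chain']}{row['position']} -> {row['pockets']} "
              f"({row['protective_residues']} vs {row['susceptible_residues']})")
    print("\npocket-1 combinations, full cohort "
          f"(family m = {len(DEFAULT_COMBOS)}):")
    for row in combo_rows:
        if row["pocket"] == "P1" and row["scope"] == "all":
            print(f"  {row['combo']}: OR {row['or']:.2f} "
                  f"({row['ci_low']:.2f}, {row['ci_high']:.2f}), "
                  f"p = {row['p']:.3g}")


if __name__ == "__main__":
    main()
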