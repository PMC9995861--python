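"""End-to-end orchestration of the analysis stages, in the order the study
design implies: frequencies and common-allele filtering, per-gene allele
association, two-locus haplotype EM and testing, the opposing-directionality
screen with candidate pocket residues, pocket-combination association,
expression-SNP association, the LD report, and TCE-group association.

Every stage is a thin wrapper over the library; outputs are TSV tables plus
a JSON manifest. Outputs are deterministic: identical inputs give identical
bytes (which is why the manifest carries a content hash rather than a
timestamp — run times go to the log).
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .association import (AssociationResult, bonferroni, fit_additive,
                          frequency, frequency_filter)
from .cohort import CASE, CONTROL, GenotypeTable, allele_dosages, \
    chromosome_counts, read_cohort
from .haplotypes import EMError, em_fit, haplotype_test, status_map
from .ld import ExpressionClassFeature, LDError, ResidueFeature, feature_ld, ld
from .registry import (ALPHA1_TRACKED, BETA1_TRACKED, Allele,
                       combined_residue_map, default_expression_map,
                       default_pockets, default_tce_map)
from .screen import (ComboError, ComboSpec, DEFAULT_COMBOS, candidate_residues,
                     combo_association, opposing_screen)

log = logging.getLogger("hlapocket")

LD_POSITIONS = (11, 36, 55, 69, 76, 84, 96, 170)


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_tsv(rows: Iterable[dict], columns: Sequence[str], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c, "")) for c in columns) + "\n")


def _scopes(table: GenotypeTable) -> list[tuple[str, GenotypeTable]]:
    scopes = [("all", table)]
    scopes += [(f"stratum:{s}", table.subset(stratum=s)) for s in table.strata]
    return scopes


def allele_frequency_stage(table: GenotypeTable, threshold: float):
    freq_rows, retained = [], {}
    for gene in table.genes:
        by_scope: dict[str, dict[str, float]] = {}
        for scope, sub in _scopes(table):
            counts = chromosome_counts(sub, gene)
            total = sum(counts.values())
            by_scope[scope] = {}
            if total == 0:
                continue
            for allele, c in sorted(counts.items()):
                by_scope[scope][str(allele)] = c / total
            for status in (CONTROL, CASE):
                scounts = chromosome_counts(sub, gene, status=status)
                stotal = sum(scounts.values())
                for allele, c in sorted(scounts.items()):
                    est = frequency(c, stotal, str(allele))
                    freq_rows.append({
                        "gene": gene, "scope": scope, "status": status,
                        "allele": str(allele), "n": c, "total": stotal,
                        "freq": est.freq, "ci_low": est.ci95[0],
                        "ci_high": est.ci95[1]})
        retained[gene] = frequency_filter(by_scope, threshold)
    return freq_rows, retained


def allele_association_stage(table: GenotypeTable,
                             retained: dict[str, list[str]], alpha: float):
    rows = []
    full_results: dict[str, list[tuple[Allele, AssociationResult]]] = {}
    for gene in table.genes:
        names = retained[gene]
        if not names:
            continue
        family = bonferroni(len(names), alpha)
        for scope, sub in _scopes(table):
            for name in names:
                allele = Allele(gene, name.split("*")[-1])
                subs, dosage = allele_dosages(sub, gene, allele)
                status = [1 if s.is_case else 0 for s in subs]
                try:
                    res = fit_additive(dosage, status, feature=str(allele))
                except ValueError as exc:
                    log.info("assoc skipped: %s [%s]: %s", allele, scope, exc)
                    continue
                if scope == "all":
                    full_results.setdefault(gene, []).append((allele, res))
                rows.append({
                    "gene": gene, "scope": scope, "allele": str(allele),
                    "or": res.or_, "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1], "p": res.p, "n": res.n_subjects,
                    "family_m": family.m, "threshold": family.threshold,
                    "significant": res.p == res.p and res.p < family.threshold,
                    "flags": ",".join(sorted(res.flags))})
    return rows, full_results


def haplotype_stage(table: GenotypeTable):
    rows = []
    estimates = {}
    for gene_a, gene_b in (("DPA1", "DPB1"), ("DQA1", "DQB1")):
        if gene_a not in table.genes or gene_b not in table.genes:
            log.warning("skipping %s~%s haplotypes: locus not typed",
                        gene_a, gene_b)
            continue
        for scope, sub in _scopes(table):
            try:
                est = em_fit(sub, gene_a, gene_b)
            except EMError as exc:
                log.warning("EM failed for %s~%s [%s]: %s",
                            gene_a, gene_b, scope, exc)
                continue
            if scope == "all":
                estimates[(gene_a, gene_b)] = est
            tests = haplotype_test(est, status_map(sub))
            family = bonferroni(len(tests))
            for t in tests:
                label = (t.haplotype if isinstance(t.haplotype, str)
                         else f"{t.haplotype[0]}~{t.haplotype[1]}")
                hap_freq = (est.freq_of(t.haplotype)
                            if not isinstance(t.haplotype, str) else float("nan"))
                rows.append({
                    "pair": f"{gene_a}~{gene_b}", "scope": scope,
                    "haplotype": label, "freq": hap_freq,
                    "case_count": t.case_count, "control_count": t.control_count,
                    "or": t.or_, "ci_low": t.ci95[0], "ci_high": t.ci95[1],
                    "p": t.p, "family_m": family.m,
                    "threshold": family.threshold,
                    "flags": ",".join(sorted(t.flags))})
    return rows, estimates


def screen_stage(full_results, alpha_screen: float = 0.05):
    rmap = combined_residue_map()
    pockets = default_pockets()
    screen_rows, candidate_rows = [], []
    for gene, chain, tracked in (("DPA1", "alpha", ALPHA1_TRACKED),
                                 ("DPB1", "beta", BETA1_TRACKED)):
        if gene not in full_results:
            continue
        sets = opposing_screen(full_results[gene], alpha_screen)
        for direction, members in (("protective", sets.protective),
                                   ("susceptible", sets.susceptible)):
            for allele, res in sorted(members.items()):
                screen_rows.append({"gene": gene, "direction": direction,
                                    "allele": str(allele), "or": res.or_,
                                    "p": res.p})
        if not sets.protective or not sets.susceptible:
            log.warning("screen found no opposing pair for %s", gene)
            continue
        try:
            cands = candidate_residues(rmap, sets, chain, tracked, pockets)
        except KeyError as exc:
            log.warning("candidate residues unavailable for %s: %s", gene, exc)
            continue
        for c in cands:
            candidate_rows.append({
                "gene": gene, "chain": chain, "position": c.position,
                "pockets": ",".join(c.pockets),
                "protective_residues": "|".join(sorted(c.protective_residues)),
                "susceptible_residues": "|".join(sorted(c.susceptible_residues))})
    return screen_rows, candidate_rows


def combo_stage(table: GenotypeTable, estimates, combos: Sequence[ComboSpec]):
    rows = []
    have_alpha = "DPA1" in table.genes
    family = bonferroni(len(combos))
    for scope, sub in _scopes(table):
        est = None
        if have_alpha:
            try:
                est = em_fit(sub, "DPA1", "DPB1")
            except EMError:
                est = None
        for spec in combos:
            if spec.needs_alpha and est is None:
                log.warning("skipping alpha+beta combo %s [%s]: DPA1 "
                            "unavailable", spec.label, scope)
                continue
            try:
                res = combo_association(sub, spec, est)
            except (ComboError, ValueError) as exc:
                log.info("combo %s [%s] skipped: %s", spec.label, scope, exc)
                continue
            rows.append({
                "combo": spec.label, "pocket": spec.pocket or "", "scope": scope,
                "or": res.or_, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                "p": res.p, "n": res.n_subjects, "family_m": family.m,
                "threshold": family.threshold,
                "significant": res.p == res.p and res.p < family.threshold,
                "flags": ",".join(sorted(res.flags))})
    return rows


def expression_stage(table: GenotypeTable):
    emap = default_expression_map()
    rows = []
    for scope, sub in _scopes(table):
        subs = sub.available("DPB1")
        for cls, label in (("A", "rs9277534_A_Low"), ("G", "rs9277534_G_High")):
            dosage = [sum(emap.infer(a) == cls for a in s.genotypes["DPB1"])
                      for s in subs]
            status = [1 if s.is_case else 0 for s in subs]
            try:
                res = fit_additive(dosage, status, feature=label)
            except ValueError as exc:
                log.info("expression %s [%s] skipped: %s", label, scope, exc)
                continue
            rows.append({"snp": label, "scope": scope, "or": res.or_,
                         "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                         "p": res.p, "n": res.n_subjects,
                         "flags": ",".join(sorted(res.flags))})
    return rows


def ld_stage(table: GenotypeTable):
    rmap = combined_residue_map()
    rows = []
    counts = chromosome_counts(table, "DPB1")
    for pos in LD_POSITIONS:
        residues = sorted({rmap.residue_at(a, "beta", pos) for a in counts})
        for res in residues:
            fx = ResidueFeature("DPB1", "beta", pos, frozenset(res))
            fy = ExpressionClassFeature("G")
            try:
                out = feature_ld(table, fx, fy)
            except LDError as exc:
                log.info("LD %s vs G skipped: %s", fx.label, exc)
                continue
            rows.append({"featureX": fx.label, "featureY": fy.label,
                         "p_A": out.p_A, "p_B": out.p_B, "p_AB": out.p_AB,
                         "D": out.D, "r2": out.r2})
    try:
        out = feature_ld(table, ResidueFeature("DPB1", "beta", 96, frozenset("K")),
                         ResidueFeature("DPB1", "beta", 170, frozenset("I")))
        rows.append({"featureX": "b96:K", "featureY": "b170:I", "p_A": out.p_A,
                     "p_B": out.p_B, "p_AB": out.p_AB, "D": out.D, "r2": out.r2})
    except LDError:
        pass
    return rows


def tce_stage(table: GenotypeTable, estimates,
              combos: Sequence[ComboSpec]):
    tmap = default_tce_map()
    rmap = combined_residue_map()
    rows, corr_rows = [], []
    family = bonferroni(3)
    for scope, sub in _scopes(table):
        subs = sub.available("DPB1")
        for group in (1, 2, 3):
            dosage = [sum(tmap.assign(a) == group for a in s.genotypes["DPB1"])
                      for s in subs]
            status = [1 if s.is_case else 0 for s in subs]
            try:
                res = fit_additive(dosage, status, feature=f"TCE:{group}")
            except ValueError as exc:
                log.info("TCE group %d [%s] skipped: %s", group, scope, exc)
                continue
            rows.append({"group": group, "scope": scope, "or": res.or_,
                         "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                         "p": res.p, "n": res.n_subjects,
                         "family_m": family.m, "threshold": family.threshold,
                         "flags": ",".join(sorted(res.flags))})
    est = estimates.get(("DPA1", "DPB1"))
    if est is not None:
        for group in (1, 3):
            for spec in combos:
                p_a = p_b = p_ab = 0.0
                try:
                    for h, f in zip(est.haplotypes, est.freqs):
                        x = tmap.assign(h[1]) == group
                        y = spec.haplotype_qualifies(*h, rmap)
                        p_a += f * x
                        p_b += f * y
                        p_ab += f * (x and y)
                    out = ld(p_ab, p_a, p_b)
                except (LDError, KeyError):
                    continue
                corr_rows.append({"tce_group": group, "combo": spec.label,
                                  "r": out.r, "r2": out.r2})
    return rows, corr_rows


def run_pipeline(cohort_path: str | Path, outdir: str | Path,
                 alpha: float = 0.05, freq_threshold: float = 0.05,
                 combos: Sequence[ComboSpec] = DEFAULT_COMBOS,
                 seed: int | None = None) -> dict:
    """Run every stage on the cohort at *cohort_path*, writing TSV tables and
    a JSON manifest under *outdir*. Returns the manifest."""
    cohort_path = Path(cohort_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_cohort(cohort_path)
    log.info("cohort: %d subjects, genes %s", len(table.subjects), table.genes)

    stages: dict[str, str] = {}

    def emit(name, rows, columns):
        path = outdir / f"{name}.tsv"
        write_tsv(rows, columns, path)
        stages[name] = f"{name}.tsv"  # relative: manifest bytes don't depend on outdir
        log.info("stage %s: %d rows", name, len(rows))

    freq_rows, retained = allele_frequency_stage(table, freq_threshold)
    emit("frequencies", freq_rows,
         ["gene", "scope", "status", "allele", "n", "total", "freq",
          "ci_low", "ci_high"])

    assoc_rows, full_results = allele_association_stage(table, retained, alpha)
    emit("allele_association", assoc_rows,
         ["gene", "scope", "allele", "or", "ci_low", "ci_high", "p", "n",
          "family_m", "threshold", "significant", "flags"])

    hap_rows, estimates = haplotype_stage(table)
    emit("haplotype_association", hap_rows,
         ["pair", "scope", "haplotype", "freq", "case_count", "control_count",
          "or", "ci_low", "ci_high", "p", "family_m", "threshold", "flags"])

    screen_rows, candidate_rows = screen_stage(full_results, alpha)
    emit("screen", screen_rows, ["gene", "direction", "allele", "or", "p"])
    emit("candidate_residues", candidate_rows,
         ["gene", "chain", "position", "pockets", "protective_residues",
          "susceptible_residues"])

    emit("combo_association", combo_stage(table, estimates, combos),
         ["combo", "pocket", "scope", "or", "ci_low", "ci_high", "p", "n",
          "family_m", "threshold", "significant", "flags"])

    emit("expression_association", expression_stage(table),
         ["snp", "scope", "or", "ci_low", "ci_high", "p", "n", "flags"])

    emit("ld_report", ld_stage(table),
         ["featureX", "featureY", "p_A", "p_B", "p_AB", "D", "r2"])

    tce_rows, tce_corr = tce_stage(table, estimates, combos)
    emit("tce_association", tce_rows,
         ["group", "scope", "or", "ci_low", "ci_high", "p", "n", "family_m",
          "threshold", "flags"])
    emit("tce_combo_correlation", tce_corr, ["tce_group", "combo", "r", "r2"])

    manifest = {
        "input": str(cohort_path),
        "input_sha256": hashlib.sha256(cohort_path.read_bytes()).hexdigest(),
        "package_version": __version__,
        "seed": seed,
        "alpha": alpha,
        "freq_threshold": freq_threshold,
        "combos": [c.label for c in combos],
        "stages": stages,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
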