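"""Cohort genotype tables: per-subject unphased two-field allele calls with
case/control status and an optional stratum label.

Missingness is handled per gene: a subject lacking a genotype at one locus is
excluded from that locus's analyses only, matching the differing per-gene
subject counts a real NGS-typed cohort shows. A half-typed genotype (one
allele present, the other blank) is treated as missing for the whole locus.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .registry import GENES, Allele, AlleleParseError, parse_allele

CASE, CONTROL = "case", "control"

_STATUS_ALIASES = {"case": CASE, "1": CASE, "control": CONTROL, "0": CONTROL}


class CohortFormatError(ValueError):
    pass


@dataclass
class SubjectRecord:
    subject_id: str
    status: str  # "case" | "control"
    stratum: str | None = None
    genotypes: dict[str, tuple[Allele, Allele]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in (CASE, CONTROL):
            raise CohortFormatError(f"bad status {self.status!r}")
        for gene, pair in self.genotypes.items():
            if any(a.gene != gene for a in pair):
                raise CohortFormatError(
                    f"{self.subject_id}: genotype pair for {gene} holds "
                    f"alleles of another gene")

    @property
    def is_case(self) -> bool:
        return self.status == CASE


@dataclass
class GenotypeTable:
    subjects: list[SubjectRecord]
    genes: list[str]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortFormatError(f"duplicate subject_id(s): {dup}")

    def subset(self, stratum: str | None = None,
               status: str | None = None) -> "GenotypeTable":
        subs = [s for s in self.subjects
                if (stratum is None or s.stratum == stratum)
                and (status is None or s.status == status)]
        return GenotypeTable(subs, list(self.genes))

    def available(self, gene: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if gene in s.genotypes]

    def n_available(self, gene: str) -> int:
        return len(self.available(gene))

    @property
    def strata(self) -> list[str]:
        return sorted({s.stratum for s in self.subjects if s.stratum is not None})


def read_cohort(path: str | Path) -> GenotypeTable:
    """Read a cohort CSV: ``subject_id,status,stratum,<gene>_1,<gene>_2,...``.

    Allele cells may carry the ``GENE*`` prefix or be bare two-field names;
    empty cells make the whole locus missing for that subject. Malformed rows
    are rejected with row-numbered messages.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortFormatError(f"{path}: empty file")
        cols = set(reader.fieldnames)
        for col in ("subject_id", "status"):
            if col not in cols:
                raise CohortFormatError(f"{path}: missing mandatory column {col!r}")
        genes = [g for g in GENES if f"{g}_1" in cols and f"{g}_2" in cols]
        if not genes:
            raise CohortFormatError(f"{path}: no <gene>_1/<gene>_2 column pairs found")
        subjects = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            status = _STATUS_ALIASES.get((row["status"] or "").strip().lower())
            if status is None:
                raise CohortFormatError(
                    f"{path} row {i}: unrecognized status {row['status']!r}")
            stratum = (row.get("stratum") or "").strip() or None
            genotypes = {}
            for gene in genes:
                c1, c2 = (row.get(f"{gene}_1") or "").strip(), (row.get(f"{gene}_2") or "").strip()
                if not c1 or not c2:
                    continue  # no half-genotypes
                try:
                    genotypes[gene] = (parse_allele(c1, gene=gene),
                                       parse_allele(c2, gene=gene))
                except AlleleParseError as exc:
                    raise CohortFormatError(f"{path} row {i}: {exc}") from exc
            subjects.append(SubjectRecord(row["subject_id"].strip(), status,
                                          stratum, genotypes))
    return GenotypeTable(subjects, genes)


def write_cohort(table: GenotypeTable, path: str | Path) -> None:
    fields = ["subject_id", "status", "stratum"]
    for g in table.genes:
        fields += [f"{g}_1", f"{g}_2"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for s in table.subjects:
            row = {"subject_id": s.subject_id, "status": s.status,
                   "stratum": s.stratum or ""}
            for g in table.genes:
                if g in s.genotypes:
                    a1, a2 = sorted(s.genotypes[g])
                    row[f"{g}_1"], row[f"{g}_2"] = str(a1), str(a2)
                else:
                    row[f"{g}_1"] = row[f"{g}_2"] = ""
            writer.writerow(row)


def chromosome_counts(table: GenotypeTable, gene: str,
                      stratum: str | None = None,
                      status: str | None = None) -> dict[Allele, int]:
    """Allele -> number of chromosomes carrying it. Each subject with a
    non-missing genotype contributes two chromosomes (homozygotes both to
    one allele)."""
    if gene not in table.genes:
        raise CohortFormatError(f"gene {gene} not in table")
    counts: dict[Allele, int] = {}
    for s in table.subset(stratum, status).available(gene):
        for a in s.genotypes[gene]:
            counts[a] = counts.get(a, 0) + 1
    return counts


def allele_dosages(table: GenotypeTable, gene: str,
                   allele: Allele) -> tuple[list[SubjectRecord], list[int]]:
    """Per-subject 0/1/2 dosage of *allele*, over subjects typed at *gene*."""
    subs = table.available(gene)
    dosages = [sum(a == allele for a in s.genotypes[gene]) for s in subs]
    return subs, dosages
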