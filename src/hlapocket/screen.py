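"""The discovery procedure: opposing-directionality candidate selection,
candidate pocket-residue derivation, and alpha+beta pocket-combination
association.

A combination ("combo") is a conjunction of residue terms, each term allowing
one of several residues at a chain position — the grammar ``a31:M + b84:G|V``
reads "alpha 31 is M AND beta 84 is G or V". Beta-only combos are counted
directly on the subject's two DPB1 allele calls; alpha+beta combos count
haplotypes whose alpha allele satisfies the alpha terms and beta allele the
beta terms *in cis*, using the subject's EM phase posterior (an
"independent" mode that pairs the two loci at random is available as a
sensitivity analysis).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .association import AssociationResult, fit_additive
from .cohort import GenotypeTable, SubjectRecord
from .haplotypes import HaplotypeFrequencyEstimate
from .registry import (Allele, AlleleResidueMap, PocketDefinitions,
                       combined_residue_map, default_pockets)


class ComboError(ValueError):
    pass


@dataclass(frozen=True)
class ComboTerm:
    chain: str  # "alpha" | "beta"
    position: int
    residues: frozenset[str]

    @property
    def label(self) -> str:
        ch = "a" if self.chain == "alpha" else "b"
        return f"{ch}{self.position}:{'|'.join(sorted(self.residues))}"

    def satisfied_by(self, allele: Allele, residue_map: AlleleResidueMap) -> bool:
        return residue_map.residue_at(allele, self.chain, self.position) in self.residues


@dataclass(frozen=True)
class ComboSpec:
    terms: tuple[ComboTerm, ...]
    pocket: str | None = None

    def __post_init__(self) -> None:
        if not self.terms:
            raise ComboError("a combo needs at least one term")

    @property
    def label(self) -> str:
        return " + ".join(t.label for t in self.terms)

    def alpha_terms(self) -> tuple[ComboTerm, ...]:
        return tuple(t for t in self.terms if t.chain == "alpha")

    def beta_terms(self) -> tuple[ComboTerm, ...]:
        return tuple(t for t in self.terms if t.chain == "beta")

    @property
    def needs_alpha(self) -> bool:
        return bool(self.alpha_terms())

    def haplotype_qualifies(self, dpa1: Allele, dpb1: Allele,
                            residue_map: AlleleResidueMap) -> bool:
        return (all(t.satisfied_by(dpa1, residue_map) for t in self.alpha_terms())
                and all(t.satisfied_by(dpb1, residue_map) for t in self.beta_terms()))


_TERM_RE = re.compile(r"^\s*([ab])\s*(\d+)\s*:\s*([A-Za-z|]+)\s*$",
                      re.IGNORECASE)


def parse_combo(text: str, pocket: str | None = None) -> ComboSpec:
    """Parse the compact grammar ``a31:M + b84:G|V`` (case-insensitive)."""
    terms = []
    for part in text.split("+"):
        m = _TERM_RE.match(part)
        if not m:
            raise ComboError(f"malformed combo term {part.strip()!r} in {text!r}")
        chain = "alpha" if m.group(1).lower() == "a" else "beta"
        residues = frozenset(r.upper() for r in m.group(3).split("|") if r)
        if not residues:
            raise ComboError(f"empty residue set in combo term {part.strip()!r}")
        terms.append(ComboTerm(chain, int(m.group(2)), residues))
    return ComboSpec(tuple(terms), pocket)


#: the ten pocket residue combinations evaluated in the DP analysis
DEFAULT_COMBOS: tuple[ComboSpec, ...] = (
    parse_combo("a31:M + b84:G|V", "P1"),
    parse_combo("a31:Q + b84:D", "P1"),
    parse_combo("a11:A + b11:G", "P6"),
    parse_combo("a11:M + b11:L", "P6"),
    parse_combo("b36:A + b55:A", "P9"),
    parse_combo("b36:V + b55:D", "P9"),
    parse_combo("b65:I + b69:K", "P7"),
    parse_combo("b65:L + b69:E", "P7"),
    parse_combo("b69:K + b76:M", "P4"),
    parse_combo("b69:E + b76:V|I", "P4"),
)


@dataclass
class DirectionalitySets:
    """Significant features split by direction of association."""
    protective: dict[Allele, AssociationResult] = field(default_factory=dict)
    susceptible: dict[Allele, AssociationResult] = field(default_factory=dict)


def opposing_screen(results: Iterable[tuple[Allele, AssociationResult]],
                    alpha_screen: float = 0.05) -> DirectionalitySets:
    """Partition features with p < alpha_screen by OR direction.

    Nomination is at the uncorrected level: the screen is a candidate
    generator, not a confirmatory test, so family correction is deliberately
    not applied here.
    """
    sets = DirectionalitySets()
    for allele, res in results:
        if not (res.p == res.p) or res.p >= alpha_screen:  # NaN-safe
            continue
        if res.or_ < 1.0:
            sets.protective[allele] = res
        elif res.or_ > 1.0:
            sets.susceptible[allele] = res
    return sets


@dataclass(frozen=True)
class CandidateResidue:
    position: int
    pockets: tuple[str, ...]
    protective_residues: frozenset[str]
    susceptible_residues: frozenset[str]


def candidate_residues(residue_map: AlleleResidueMap, sets: DirectionalitySets,
                       chain: str, positions: Iterable[int],
                       pockets: PocketDefinitions | None = None
                       ) -> list[CandidateResidue]:
    """Pocket positions where protective and susceptible alleles carry
    different residue sets, annotated with every pocket containing them."""
    if not sets.protective or not sets.susceptible:
        raise ComboError("both directionality sets must be non-empty")
    if pockets is None:
        pockets = default_pockets()
    out = []
    for pos in sorted(positions):
        res_p = {residue_map.residue_at(a, chain, pos) for a in sets.protective}
        res_s = {residue_map.residue_at(a, chain, pos) for a in sets.susceptible}
        if res_p == res_s:
            continue
        pks = pockets.pockets_of(chain, pos)
        if not pks:
            continue
        out.append(CandidateResidue(pos, pks, frozenset(res_p), frozenset(res_s)))
    return out


def combo_dosage(subject: SubjectRecord, spec: ComboSpec,
                 est: HaplotypeFrequencyEstimate | None = None,
                 residue_map: AlleleResidueMap | None = None,
                 mode: str = "cis") -> float:
    """Expected number of chromosomes (0..2) satisfying *spec* for one subject.

    Beta-only combos count the DPB1 alleles satisfying every beta term.
    Alpha+beta combos count cis DPA1~DPB1 haplotypes: in ``cis`` mode the
    count is averaged over the subject's EM phase posterior; ``independent``
    mode pairs the two loci at random (each pairing weight 1/2).
    """
    if residue_map is None:
        residue_map = combined_residue_map()
    if not spec.needs_alpha:
        if "DPB1" not in subject.genotypes:
            raise ComboError(f"{subject.subject_id}: DPB1 genotype missing")
        beta = spec.beta_terms()
        return float(sum(
            all(t.satisfied_by(b, residue_map) for t in beta)
            for b in subject.genotypes["DPB1"]))
    if "DPA1" not in subject.genotypes or "DPB1" not in subject.genotypes:
        raise ComboError(f"{subject.subject_id}: DPA1/DPB1 genotype missing")
    if mode == "independent":
        a_sat = sum(all(t.satisfied_by(a, residue_map)
                        for t in spec.alpha_terms())
                    for a in subject.genotypes["DPA1"])
        b_sat = sum(all(t.satisfied_by(b, residue_map)
                        for t in spec.beta_terms())
                    for b in subject.genotypes["DPB1"])
        return a_sat * b_sat / 2.0
    if mode != "cis":
        raise ComboError(f"unknown combo dosage mode {mode!r}")
    if est is None or subject.subject_id not in est.posteriors:
        raise ComboError(
            f"cis dosage for {subject.subject_id} needs an EM phase posterior")
    dose = 0.0
    for (h1, h2), p in est.posteriors[subject.subject_id]:
        dose += p * (spec.haplotype_qualifies(*h1, residue_map)
                     + spec.haplotype_qualifies(*h2, residue_map))
    return dose


def combo_association(table: GenotypeTable, spec: ComboSpec,
                      est: HaplotypeFrequencyEstimate | None = None,
                      residue_map: AlleleResidueMap | None = None,
                      mode: str = "cis") -> AssociationResult:
    """Additive logistic fit of case status on the combo dosage."""
    needed = ("DPA1", "DPB1") if spec.needs_alpha else ("DPB1",)
    subjects = [s for s in table.subjects
                if all(g in s.genotypes for g in needed)]
    if spec.needs_alpha and mode == "cis":
        subjects = [s for s in subjects
                    if est is not None and s.subject_id in est.posteriors]
    if not subjects:
        raise ComboError("no subjects with the genotypes the combo needs")
    dosage = [combo_dosage(s, spec, est, residue_map, mode) for s in subjects]
    status = [1 if s.is_case else 0 for s in subjects]
    return fit_additive(dosage, status, feature=spec.label)
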