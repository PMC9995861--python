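"""Linkage disequilibrium between chromosome-level binary features.

Features are deterministic functions of an allele call: a residue at a
mature-protein position, the rs9277534 expression class (inferred from the
DPB1 allele), a TCE group, or allele identity itself. Within one gene both
features ride the same allele call, so no phase inference is needed; a
DPA1-vs-DPB1 pair is evaluated on EM-estimated haplotype frequencies.

D = p_AB - p_A p_B and R^2 = D^2 / (p_A (1-p_A) p_B (1-p_B)).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import GenotypeTable, chromosome_counts
from .haplotypes import HaplotypeFrequencyEstimate
from .registry import (Allele, AlleleResidueMap, ExpressionSNPMap, TCEMap,
                       combined_residue_map, default_expression_map,
                       default_tce_map)


class LDError(ValueError):
    pass


@dataclass(frozen=True)
class LDResult:
    p_AB: float
    p_A: float
    p_B: float
    D: float
    r2: float

    @property
    def r(self) -> float:
        """Signed correlation coefficient (phi)."""
        return math.copysign(math.sqrt(self.r2), self.D) if self.D else 0.0


def ld(p_AB: float, p_A: float, p_B: float) -> LDResult:
    if not (0.0 < p_A < 1.0 and 0.0 < p_B < 1.0):
        raise LDError(f"degenerate marginal frequency: p_A={p_A}, p_B={p_B}")
    lo, hi = max(0.0, p_A + p_B - 1.0), min(p_A, p_B)
    if not (lo - 1e-12 <= p_AB <= hi + 1e-12):
        raise LDError(f"p_AB={p_AB} outside Frechet bounds [{lo}, {hi}]")
    D = p_AB - p_A * p_B
    if p_AB == p_A == p_B or (p_AB == 0.0 and p_A + p_B == 1.0):
        # perfect (anti-)correspondence: exact by definition, do not let
        # floating-point cancellation shave the last ulp off 1.0
        return LDResult(p_AB, p_A, p_B, D, 1.0)
    r2 = D * D / (p_A * (1.0 - p_A) * p_B * (1.0 - p_B))
    return LDResult(p_AB, p_A, p_B, D, min(r2, 1.0))


# --- chromosome-level binary features --------------------------------------

@dataclass(frozen=True)
class ResidueFeature:
    gene: str
    chain: str
    position: int
    residues: frozenset[str]
    _map: AlleleResidueMap | None = None

    def __call__(self, allele: Allele) -> bool:
        m = self._map if self._map is not None else combined_residue_map()
        return m.residue_at(allele, self.chain, self.position) in self.residues

    @property
    def label(self) -> str:
        ch = "a" if self.chain == "alpha" else "b"
        return f"{ch}{self.position}:{'|'.join(sorted(self.residues))}"


@dataclass(frozen=True)
class ExpressionClassFeature:
    snp_class: str  # "A" (low) or "G" (high)
    gene: str = "DPB1"
    _map: ExpressionSNPMap | None = None

    def __call__(self, allele: Allele) -> bool:
        m = self._map if self._map is not None else default_expression_map()
        return m.infer(allele) == self.snp_class

    @property
    def label(self) -> str:
        return f"rs9277534:{self.snp_class}"


@dataclass(frozen=True)
class TCEGroupFeature:
    group: int
    gene: str = "DPB1"
    _map: TCEMap | None = None

    def __call__(self, allele: Allele) -> bool:
        m = self._map if self._map is not None else default_tce_map()
        return m.assign(allele) == self.group

    @property
    def label(self) -> str:
        return f"TCE:{self.group}"


@dataclass(frozen=True)
class AlleleFeature:
    allele: Allele

    @property
    def gene(self) -> str:
        return self.allele.gene

    def __call__(self, allele: Allele) -> bool:
        return allele == self.allele

    @property
    def label(self) -> str:
        return str(self.allele)


def feature_ld(table: GenotypeTable, feature_x, feature_y,
               est: HaplotypeFrequencyEstimate | None = None) -> LDResult:
    """LD between two chromosome-level features.

    Same-gene pairs are counted directly over that gene's allele calls.
    Cross-gene (DPA1 x DPB1) pairs need phased chromosomes, so the joint and
    marginal frequencies are taken from the EM haplotype-frequency estimate
    *est* (required in that case).
    """
    gx, gy = feature_x.gene, feature_y.gene
    if gx == gy:
        counts = chromosome_counts(table, gx)
        total = sum(counts.values())
        if total == 0:
            raise LDError(f"no chromosomes typed at {gx}")
        p_a = sum(c for a, c in counts.items() if feature_x(a)) / total
        p_b = sum(c for a, c in counts.items() if feature_y(a)) / total
        p_ab = sum(c for a, c in counts.items()
                   if feature_x(a) and feature_y(a)) / total
        return ld(p_ab, p_a, p_b)
    if est is None:
        raise LDError("cross-gene LD needs an EM haplotype frequency estimate")
    fx_side = 0 if gx == est.haplotypes[0][0].gene else 1
    fy_side = 0 if gy == est.haplotypes[0][0].gene else 1
    p_a = p_b = p_ab = 0.0
    for h, f in zip(est.haplotypes, est.freqs):
        x = feature_x(h[fx_side])
        y = feature_y(h[fy_side])
        p_a += f * x
        p_b += f * y
        p_ab += f * (x and y)
    return ld(p_ab, p_a, p_b)


def ld_report_row(feature_x, feature_y, result: LDResult) -> dict:
    return {"featureX": feature_x.label, "featureY": feature_y.label,
            "p_A": result.p_A, "p_B": result.p_B, "p_AB": result.p_AB,
            "D": result.D, "r2": result.r2}
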