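"""Domain knowledge as data: allele nomenclature, residue maps, pocket
definitions, rs9277534 expression classes and TCE groups.

All residue coordinates use mature-protein numbering (position 1 = first
residue after the signal peptide), the IPD-IMGT/HLA convention. Alleles are
handled at two-field resolution; higher fields and expression suffixes are
truncated on parse.

The packaged maps ship as plain-text TSV files under ``hlapocket/data`` with
``#provenance=`` and ``#coordinate=`` header lines; user-supplied updates in
the same format can be loaded with the ``load_*`` functions.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

GENES = ("DRB1", "DQA1", "DQB1", "DPA1", "DPB1")
CHAINS = ("alpha", "beta")
POCKETS = ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "P9")

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_NAME_RE = re.compile(r"^\d{2,3}:\d{2,3}$")
_RAW_RE = re.compile(
    r"^(?P<gene>[A-Z0-9]+)\*(?P<f1>\d{2,3}):(?P<f2>\d{2,3})"
    r"(?::\d{2,3})*(?P<suffix>[NLSCAQ]?)$"
)

#: beta1-domain positions tracked for the opposing-directionality screen
BETA1_TRACKED = frozenset({8, 9, 11, 36, 55, 56, 57, 65, 69, 76, 84, 85, 86, 87})
#: alpha1-domain positions tracked for the screen
ALPHA1_TRACKED = frozenset({11, 31, 66})


class RegistryError(KeyError):
    """Lookup failure in a packaged or user-supplied mapping table."""


class AlleleParseError(ValueError):
    """Raised when an allele string cannot be parsed."""


@dataclass(frozen=True, order=True)
class Allele:
    """A two-field HLA Class II allele, e.g. ``Allele("DPB1", "04:01")``."""

    gene: str
    name: str

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise AlleleParseError(f"unknown HLA Class II gene: {self.gene!r}")
        if not _NAME_RE.match(self.name):
            raise AlleleParseError(f"not a two-field allele name: {self.name!r}")

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.gene}*{self.name}"


def parse_allele(raw: str, gene: str | None = None) -> Allele:
    """Parse ``GENE*ff:ff[:ff[:ff]][suffix]`` (or a bare ``ff:ff`` when
    *gene* is given) to a two-field :class:`Allele`.

    Higher fields and expression suffixes are truncated: two-field
    resolution captures the protein sequence, which is the unit of analysis.
    """
    raw = raw.strip()
    if "*" not in raw:
        if gene is None:
            raise AlleleParseError(f"no gene prefix in {raw!r} and no gene given")
        m = re.match(r"^(\d{2,3}):(\d{2,3})(?::\d{2,3})*[NLSCAQ]?$", raw)
        if not m:
            raise AlleleParseError(f"malformed allele name: {raw!r}")
        return Allele(gene, f"{m.group(1)}:{m.group(2)}")
    m = _RAW_RE.match(raw)
    if not m:
        raise AlleleParseError(f"malformed allele string: {raw!r}")
    g = m.group("gene")
    if g not in GENES:
        raise AlleleParseError(f"unknown gene token {g!r} in {raw!r}")
    if gene is not None and g != gene:
        raise AlleleParseError(f"allele {raw!r} does not belong to gene {gene}")
    return Allele(g, f"{m.group('f1')}:{m.group('f2')}")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("hlapocket").joinpath("data", name)))


def _read_tsv(path: str | Path) -> tuple[dict[str, str], list[dict[str, str]]]:
    meta: dict[str, str] = {}
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k] = v
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
            else:
                rows.append(dict(zip(header, parts)))
    return meta, rows


class AlleleResidueMap:
    """Mapping (allele, chain, mature-protein position) -> one-letter residue."""

    def __init__(self, entries: Mapping[tuple[Allele, str, int], str],
                 provenance: str = ""):
        for (allele, chain, pos), res in entries.items():
            if chain not in CHAINS:
                raise ValueError(f"bad chain {chain!r}")
            if res not in _AA:
                raise ValueError(f"invalid residue code {res!r} at {allele} {chain}{pos}")
        self.entries = dict(entries)
        self.provenance = provenance

    def alleles(self, chain: str | None = None) -> set[Allele]:
        return {a for (a, c, _p) in self.entries if chain is None or c == chain}

    def positions(self, chain: str) -> set[int]:
        return {p for (_a, c, p) in self.entries if c == chain}

    def residue_at(self, allele: Allele, chain: str, position: int) -> str:
        try:
            return self.entries[(allele, chain, position)]
        except KeyError:
            raise RegistryError(
                f"no residue for {allele} {chain} position {position} in map"
            ) from None


def residue_at(map: AlleleResidueMap, allele: Allele, chain: str, position: int) -> str:
    return map.residue_at(allele, chain, position)


def load_residue_map(path: str | Path, gene: str) -> AlleleResidueMap:
    meta, rows = _read_tsv(path)
    entries = {}
    for row in rows:
        a = parse_allele(row["allele"], gene=gene)
        entries[(a, row["chain"], int(row["position"]))] = row["residue"]
    return AlleleResidueMap(entries, provenance=meta.get("provenance", str(path)))


class PocketDefinitions:
    """Pocket -> chain -> set of mature-protein positions (P1..P9)."""

    def __init__(self, table: Mapping[tuple[str, str], frozenset[int]]):
        for (pk, ch) in table:
            if pk not in POCKETS or ch not in CHAINS:
                raise ValueError(f"bad pocket/chain {(pk, ch)!r}")
        self.table = {k: frozenset(v) for k, v in table.items()}

    def positions(self, pocket: str, chain: str) -> frozenset[int]:
        if pocket not in POCKETS:
            raise RegistryError(f"unknown pocket {pocket!r}")
        return self.table.get((pocket, chain), frozenset())

    def pockets_of(self, chain: str, position: int) -> tuple[str, ...]:
        return tuple(pk for pk in POCKETS if position in self.positions(pk, chain))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#provenance=serialized by hlapocket\n#coordinate=mature\n")
            fh.write("pocket\tchain\tpositions\n")
            for pk in POCKETS:
                for ch in CHAINS:
                    pos = sorted(self.positions(pk, ch))
                    fh.write(f"{pk}\t{ch}\t{','.join(map(str, pos))}\n")


def load_pockets(path: str | Path) -> PocketDefinitions:
    _meta, rows = _read_tsv(path)
    table = {}
    for row in rows:
        pos = frozenset(int(x) for x in row["positions"].split(",") if x)
        table[(row["pocket"], row["chain"])] = pos
    return PocketDefinitions(table)


class ExpressionSNPMap:
    """DPB1 allele -> rs9277534 class (A = low expression, G = high)."""

    def __init__(self, entries: Mapping[Allele, str], provenance: str = ""):
        for a, cls in entries.items():
            if a.gene != "DPB1":
                raise ValueError("rs9277534 is inferable from DPB1 only")
            if cls not in ("A", "G"):
                raise ValueError(f"bad rs9277534 class {cls!r}")
        self.entries = dict(entries)
        self.provenance = provenance

    def infer(self, allele: Allele) -> str:
        try:
            return self.entries[allele]
        except KeyError:
            raise RegistryError(
                f"unknown expression class: {allele} not in rs9277534 map"
            ) from None


def infer_expression_snp(map: ExpressionSNPMap, allele: Allele) -> str:
    return map.infer(allele)


def load_expression_map(path: str | Path) -> ExpressionSNPMap:
    meta, rows = _read_tsv(path)
    entries = {parse_allele(r["allele"], gene="DPB1"): r["class"] for r in rows}
    return ExpressionSNPMap(entries, provenance=meta.get("provenance", str(path)))


class TCEMap:
    """DPB1 allele -> T-cell epitope group (1/2/3), with an exon-2 sequence
    fallback for novel alleles sharing exon 2 with a known allele."""

    def __init__(self, entries: Mapping[Allele, int],
                 fallback: Mapping[str, int] | None = None, provenance: str = ""):
        for a, g in entries.items():
            if a.gene != "DPB1" or g not in (1, 2, 3):
                raise ValueError(f"bad TCE entry {a} -> {g}")
        self.entries = dict(entries)
        self.fallback = dict(fallback or {})
        self.provenance = provenance

    def assign(self, allele: Allele, exon2_seq: str | None = None) -> int:
        if allele in self.entries:
            return self.entries[allele]
        if exon2_seq is not None and exon2_seq in self.fallback:
            return self.fallback[exon2_seq]
        raise RegistryError(f"TCE group unassigned for {allele}")


def tce_assign(map: TCEMap, allele: Allele, exon2_seq: str | None = None) -> int:
    return map.assign(allele, exon2_seq)


def load_tce_map(groups_path: str | Path, exon2_path: str | Path | None = None) -> TCEMap:
    meta, rows = _read_tsv(groups_path)
    entries = {parse_allele(r["allele"], gene="DPB1"): int(r["group"]) for r in rows}
    fallback: dict[str, int] = {}
    if exon2_path is not None:
        _m, seq_rows = _read_tsv(exon2_path)
        for r in seq_rows:
            a = parse_allele(r["allele"], gene="DPB1")
            if a in entries:
                fallback[r["sequence"]] = entries[a]
    return TCEMap(entries, fallback, provenance=meta.get("provenance", ""))


def differing_pocket_residues(map: AlleleResidueMap,
                              group_a: Iterable[Allele],
                              group_b: Iterable[Allele],
                              chain: str,
                              positions: Iterable[int]) -> set[int]:
    """Positions (within *positions*) where the residue set carried by
    *group_a* differs from the residue set carried by *group_b*.

    "Differs" is set inequality, not disjointness: a position counts when at
    least one group carries a residue the other does not. This matches how
    opposing allele groups are contrasted in the screen — e.g. DPB1*04:01 vs
    {06:01, 18:01, 104:01} differ at 14 beta1 positions even though 18:01
    shares beta11 G and beta69 K with 04:01. Symmetric in the two groups;
    identical groups differ nowhere.
    """
    ga, gb = list(group_a), list(group_b)
    out = set()
    for pos in positions:
        res_a = {map.residue_at(a, chain, pos) for a in ga}
        res_b = {map.residue_at(b, chain, pos) for b in gb}
        if res_a != res_b:
            out.add(pos)
    return out


def pocket_positions(pocket: str, chain: str,
                     pockets: PocketDefinitions | None = None) -> frozenset[int]:
    if pockets is None:
        pockets = default_pockets()
    return pockets.positions(pocket, chain)


# ---------------------------------------------------------------------------
# packaged defaults (cached)

_cache: dict[str, object] = {}


def default_pockets() -> PocketDefinitions:
    if "pockets" not in _cache:
        _cache["pockets"] = load_pockets(_data_path("pockets.tsv"))
    return _cache["pockets"]  # type: ignore[return-value]


def default_residue_map(gene: str) -> AlleleResidueMap:
    key = f"residues_{gene}"
    if key not in _cache:
        fname = {"DPB1": "dpb1_beta_residues.tsv", "DPA1": "dpa1_alpha_residues.tsv"}[gene]
        _cache[key] = load_residue_map(_data_path(fname), gene)
    return _cache[key]  # type: ignore[return-value]


def combined_residue_map() -> AlleleResidueMap:
    """DPA1 (alpha) and DPB1 (beta) maps merged into one lookup table."""
    if "residues_combined" not in _cache:
        entries = {}
        entries.update(default_residue_map("DPA1").entries)
        entries.update(default_residue_map("DPB1").entries)
        _cache["residues_combined"] = AlleleResidueMap(
            entries, provenance="hlapocket packaged DPA1+DPB1 maps")
    return _cache["residues_combined"]  # type: ignore[return-value]


def default_expression_map() -> ExpressionSNPMap:
    if "expression" not in _cache:
        _cache["expression"] = load_expression_map(_data_path("rs9277534.tsv"))
    return _cache["expression"]  # type: ignore[return-value]


def default_tce_map() -> TCEMap:
    if "tce" not in _cache:
        _cache["tce"] = load_tce_map(_data_path("tce_groups.tsv"),
                                     _data_path("dpb1_exon2.tsv"))
    return _cache["tce"]  # type: ignore[return-value]
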