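"""Synthetic case-control cohorts with the statistical structure the
analysis assumes, so every pipeline stage is testable without any download.

Per subject the generator draws a stratum, two DPA1~DPB1 haplotypes i.i.d.
from the stratum's haplotype-frequency table (Hardy-Weinberg), and the other
genes' alleles independently (linkage equilibrium across loci); computes a
linear predictor baseline + sum(effect x true dosage) from the *phased*
truth; draws case status Bernoulli(logistic(lp)); applies per-gene
missing-completely-at-random masks; and unphases. The phased truth ledger is
kept alongside the emitted table.

Draw order (one integer seed governs everything): strata for all subjects;
then, stratum by stratum in declared order, haplotype pairs and then each
non-DP gene's allele pairs in table gene order; then case status; then one
missingness mask per gene in table gene order. Identical configs and seeds
give byte-identical cohorts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from .cohort import CASE, CONTROL, GenotypeTable, SubjectRecord, write_cohort
from .registry import Allele, combined_residue_map, default_expression_map, \
    default_tce_map, parse_allele
from .screen import ComboSpec, parse_combo

OTHER_GENES = ("DRB1", "DQA1", "DQB1")


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n_subjects: int
    case_fraction: float
    strata: list[tuple[str, float]]
    # stratum -> {(dpa1 name, dpb1 name): frequency}
    dp_haplotypes: dict[str, dict[tuple[str, str], float]]
    # stratum -> gene -> {allele name: frequency}
    allele_freqs: dict[str, dict[str, dict[str, float]]]
    effects: list[tuple[str, float]] = field(default_factory=list)
    baseline_log_odds: float = 0.0
    missingness: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if abs(sum(w for _l, w in self.strata) - 1.0) > 1e-9:
            raise ConfigError("stratum weights must sum to 1")
        for label, _w in self.strata:
            for name, tab in [("dp_haplotypes", self.dp_haplotypes.get(label)),
                              *[(g, self.allele_freqs.get(label, {}).get(g))
                                for g in self.allele_freqs.get(label, {})]]:
                if tab is None:
                    continue
                total = sum(tab.values())
                if abs(total - 1.0) > 1e-6 or min(tab.values()) < 0:
                    raise ConfigError(
                        f"frequency table {name!r} for stratum {label!r} "
                        f"sums to {total}, not 1")


@dataclass
class SubjectTruth:
    stratum: str
    hap1: tuple[Allele, Allele]
    hap2: tuple[Allele, Allele]
    dosages: dict[str, float]
    lp: float


@dataclass
class GeneratedCohort:
    table: GenotypeTable
    truth: dict[str, SubjectTruth]
    config: GeneratorConfig

    def write(self, cohort_path: str | Path,
              truth_path: str | Path | None = None) -> None:
        write_cohort(self.table, cohort_path)
        if truth_path is not None:
            effect_labels = [f for f, _b in self.config.effects]
            with open(truth_path, "w", encoding="utf-8") as fh:
                cols = ["subject_id", "stratum", "status", "hap1", "hap2", "lp"]
                cols += [f"dosage[{f}]" for f in effect_labels]
                fh.write("\t".join(cols) + "\n")
                for s in self.table.subjects:
                    t = self.truth[s.subject_id]
                    row = [s.subject_id, t.stratum, s.status,
                           f"{t.hap1[0]}~{t.hap1[1]}", f"{t.hap2[0]}~{t.hap2[1]}",
                           f"{t.lp:.6g}"]
                    row += [f"{t.dosages[f]:.6g}" for f in effect_labels]
                    fh.write("\t".join(row) + "\n")


# --- effect features -------------------------------------------------------

def _feature_fn(spec: str) -> Callable[[SubjectTruth, dict[str, tuple[Allele, Allele]]], float]:
    """Resolve an effect feature spec to a true-dosage function.

    Supported specs: an allele ("DPB1*04:01"), a DPA1~DPB1 haplotype
    ("DPA1*01:03~DPB1*04:01"), a pocket combo in the compact grammar
    ("a31:M + b84:G|V"), an expression class ("rs9277534:G"), or a TCE group
    ("TCE:3"). Dosages are computed on the phased truth, so alpha+beta
    combos are exact cis counts.
    """
    spec = spec.strip()
    if spec.upper().startswith("RS9277534:"):
        cls = spec.split(":", 1)[1].strip().upper()
        emap = default_expression_map()
        return lambda t, g: float(sum(emap.infer(h[1]) == cls
                                      for h in (t.hap1, t.hap2)))
    if spec.upper().startswith("TCE:"):
        group = int(spec.split(":", 1)[1])
        tmap = default_tce_map()
        return lambda t, g: float(sum(tmap.assign(h[1]) == group
                                      for h in (t.hap1, t.hap2)))
    if "~" in spec:
        a_s, b_s = spec.split("~")
        hap = (parse_allele(a_s, gene="DPA1"), parse_allele(b_s, gene="DPB1"))
        return lambda t, g: float((t.hap1 == hap) + (t.hap2 == hap))
    if "*" in spec:
        allele = parse_allele(spec)
        if allele.gene in ("DPA1", "DPB1"):
            side = 0 if allele.gene == "DPA1" else 1
            return lambda t, g: float((t.hap1[side] == allele)
                                      + (t.hap2[side] == allele))
        return lambda t, g: float(sum(a == allele for a in g.get(allele.gene, ())))
    combo: ComboSpec = parse_combo(spec)
    rmap = combined_residue_map()
    return lambda t, g: float(
        combo.haplotype_qualifies(*t.hap1, rmap)
        + combo.haplotype_qualifies(*t.hap2, rmap))


def expected_dosage(config: GeneratorConfig, feature: str) -> float:
    """Population-average true dosage of *feature* under the config tables
    (used to center the baseline so the case fraction lands on target)."""
    if "*" in feature and "~" not in feature:
        allele = parse_allele(feature)
        if allele.gene in OTHER_GENES:
            return sum(w * 2.0 * config.allele_freqs[label]
                       .get(allele.gene, {}).get(allele.name, 0.0)
                       for label, w in config.strata)
    fn = _feature_fn(feature)
    total = 0.0
    for label, w in config.strata:
        for (a_s, b_s), f in config.dp_haplotypes[label].items():
            hap = (parse_allele(a_s, gene="DPA1"), parse_allele(b_s, gene="DPB1"))
            t = SubjectTruth(label, hap, hap, {}, 0.0)
            # fn on a double-carrier returns 2 x qualify(h)
            total += w * f * fn(t, {})
    return total


def _lp_shift_distribution(config: GeneratorConfig) -> list[tuple[float, float]]:
    """Exact distribution of sum(effect x dosage) under the config tables:
    DP-borne effects enumerated over haplotype pairs within each stratum,
    non-DP allele effects convolved as independent binomial(2, p) dosages."""
    dp_effects = [(feat, beta, _feature_fn(feat))
                  for feat, beta in config.effects
                  if not ("*" in feat and "~" not in feat
                          and parse_allele(feat).gene in OTHER_GENES)]
    other_effects = [(parse_allele(feat), beta) for feat, beta in config.effects
                     if "*" in feat and "~" not in feat
                     and parse_allele(feat).gene in OTHER_GENES]
    dist: dict[float, float] = {}
    for label, w in config.strata:
        haps, fs = [], []
        for (a_s, b_s), f in config.dp_haplotypes[label].items():
            haps.append((parse_allele(a_s, gene="DPA1"),
                         parse_allele(b_s, gene="DPB1")))
            fs.append(f)
        # per-haplotype contribution to the linear predictor
        contrib = []
        for h in haps:
            t = SubjectTruth(label, h, h, {}, 0.0)
            contrib.append(sum(beta * fn(t, {}) / 2.0
                               for _feat, beta, fn in dp_effects))
        stratum_dist: dict[float, float] = {}
        for c1, f1 in zip(contrib, fs):
            for c2, f2 in zip(contrib, fs):
                v = c1 + c2
                stratum_dist[v] = stratum_dist.get(v, 0.0) + f1 * f2
        for allele, beta in other_effects:
            p = config.allele_freqs.get(label, {}).get(
                allele.gene, {}).get(allele.name, 0.0)
            binom = {0.0: (1 - p) ** 2, beta: 2 * p * (1 - p), 2 * beta: p * p}
            new: dict[float, float] = {}
            for v, pv in stratum_dist.items():
                for dv, pd in binom.items():
                    new[v + dv] = new.get(v + dv, 0.0) + pv * pd
            stratum_dist = new
        for v, pv in stratum_dist.items():
            dist[v] = dist.get(v, 0.0) + w * pv
    return sorted(dist.items())


def baseline_for_case_fraction(config: GeneratorConfig) -> float:
    """Baseline log-odds putting the marginal case fraction on target given
    the planted effects, solved exactly over the dosage distribution."""
    from scipy.optimize import brentq

    target = config.case_fraction
    dist = _lp_shift_distribution(config)

    def gap(b: float) -> float:
        return sum(p / (1.0 + math.exp(-(b + v))) for v, p in dist) - target

    return float(brentq(gap, -30.0, 30.0, xtol=1e-12))


# --- generation ------------------------------------------------------------

def generate(config: GeneratorConfig, seed: int | None = None) -> GeneratedCohort:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    labels = [l for l, _w in config.strata]
    weights = np.array([w for _l, w in config.strata])
    stratum_idx = rng.choice(len(labels), size=n, p=weights)

    hap_of: list[tuple[tuple[Allele, Allele], tuple[Allele, Allele]]] = [None] * n  # type: ignore
    geno_of: list[dict[str, tuple[Allele, Allele]]] = [dict() for _ in range(n)]
    for si, label in enumerate(labels):
        idx = np.flatnonzero(stratum_idx == si)
        if idx.size == 0:
            continue
        hap_tab = config.dp_haplotypes[label]
        haps = [(parse_allele(a, gene="DPA1"), parse_allele(b, gene="DPB1"))
                for (a, b) in hap_tab]
        probs = np.array(list(hap_tab.values()))
        draws = rng.choice(len(haps), size=(idx.size, 2), p=probs)
        for k, i in enumerate(idx):
            hap_of[i] = (haps[draws[k, 0]], haps[draws[k, 1]])
        for gene in OTHER_GENES:
            tab = config.allele_freqs.get(label, {}).get(gene)
            if not tab:
                continue
            alleles = [parse_allele(name, gene=gene) for name in tab]
            aprobs = np.array(list(tab.values()))
            adraws = rng.choice(len(alleles), size=(idx.size, 2), p=aprobs)
            for k, i in enumerate(idx):
                geno_of[i][gene] = (alleles[adraws[k, 0]], alleles[adraws[k, 1]])

    effect_fns = [(feat, beta, _feature_fn(feat))
                  for feat, beta in config.effects]
    lps = np.full(n, config.baseline_log_odds)
    truth: dict[str, SubjectTruth] = {}
    dosages_all: list[dict[str, float]] = []
    for i in range(n):
        t = SubjectTruth(labels[stratum_idx[i]], hap_of[i][0], hap_of[i][1],
                         {}, 0.0)
        for feat, beta, fn in effect_fns:
            d = fn(t, geno_of[i])
            t.dosages[feat] = d
            lps[i] += beta * d
        t.lp = float(lps[i])
        dosages_all.append(t.dosages)
        truth[f"S{i:05d}"] = t

    status = rng.random(n) < 1.0 / (1.0 + np.exp(-lps))
    missing = {gene: rng.random(n) < config.missingness.get(gene, 0.0)
               for gene in ("DRB1", "DQA1", "DQB1", "DPA1", "DPB1")}

    subjects = []
    for i in range(n):
        sid = f"S{i:05d}"
        t = truth[sid]
        genotypes: dict[str, tuple[Allele, Allele]] = {}
        dp_pairs = {"DPA1": tuple(sorted((t.hap1[0], t.hap2[0]))),
                    "DPB1": tuple(sorted((t.hap1[1], t.hap2[1])))}
        for gene, pair in {**geno_of[i], **dp_pairs}.items():
            if not missing[gene][i]:
                genotypes[gene] = tuple(sorted(pair))  # type: ignore[assignment]
        subjects.append(SubjectRecord(
            sid, CASE if status[i] else CONTROL, t.stratum, genotypes))
    genes = [g for g in ("DRB1", "DQA1", "DQB1", "DPA1", "DPB1")
             if any(g in s.genotypes for s in subjects)]
    return GeneratedCohort(GenotypeTable(subjects, genes), truth, config)


# --- the packaged study-like default ---------------------------------------

def _norm(tab: dict, pseudo_key) -> dict:
    """Top up a frequency table with remainder mass on a pseudo entry."""
    total = sum(tab.values())
    if total > 1.0 + 1e-9:
        raise ConfigError(f"table mass {total} exceeds 1")
    out = dict(tab)
    out[pseudo_key] = out.get(pseudo_key, 0.0) + (1.0 - total)
    return out

_WHITE_DP = _norm({
    ("01:03", "04:01"): 0.420, ("01:03", "02:01"): 0.140,
    ("01:03", "04:02"): 0.120, ("01:03", "03:01"): 0.100,
    ("01:03", "06:01"): 0.013, ("01:03", "104:01"): 0.005,
    ("01:03", "18:01"): 0.002,
    ("02:01", "01:01"): 0.055, ("02:01", "17:01"): 0.018,
    ("02:01", "13:01"): 0.015, ("02:01", "14:01"): 0.010,
    ("02:01", "10:01"): 0.008, ("02:01", "09:01"): 0.008,
    ("02:01", "11:01"): 0.007,
    ("02:02", "01:01"): 0.016, ("02:02", "05:01"): 0.006,
    ("03:01", "04:02"): 0.008, ("03:01", "105:01"): 0.003,
}, ("99:99", "99:99"))

_BLACK_DP = _norm({
    ("01:03", "04:01"): 0.205, ("01:03", "02:01"): 0.095,
    ("01:03", "04:02"): 0.055, ("01:03", "03:01"): 0.045,
    ("01:03", "18:01"): 0.048, ("01:03", "06:01"): 0.012,
    ("01:03", "104:01"): 0.010,
    ("02:01", "01:01"): 0.165, ("02:01", "17:01"): 0.045,
    ("02:01", "131:01"): 0.008, ("02:01", "09:01"): 0.008,
    ("02:01", "13:01"): 0.008,
    ("02:02", "01:01"): 0.125, ("02:02", "05:01"): 0.020,
    ("03:01", "04:02"): 0.040, ("03:01", "105:01"): 0.015,
}, ("99:99", "99:99"))

_WHITE_AF = {
    "DRB1": _norm({"01:01": 0.09, "03:01": 0.11, "04:01": 0.09, "04:04": 0.02,
                   "07:01": 0.14, "09:01": 0.01, "11:01": 0.05, "11:04": 0.05,
                   "12:01": 0.02, "13:01": 0.05, "13:02": 0.04, "15:01": 0.10},
                  "99:99"),
    "DQA1": _norm({"01:01": 0.11, "01:02": 0.18, "01:03": 0.07, "01:05": 0.01,
                   "02:01": 0.14, "03:01": 0.08, "03:03": 0.07, "04:01": 0.04,
                   "05:01": 0.08, "05:05": 0.07}, "99:99"),
    "DQB1": _norm({"02:01": 0.11, "02:02": 0.09, "03:01": 0.19, "03:02": 0.09,
                   "03:03": 0.06, "03:19": 0.01, "04:02": 0.04, "05:01": 0.13,
                   "06:02": 0.10, "06:03": 0.05}, "99:99"),
}

_BLACK_AF = {
    "DRB1": _norm({"01:01": 0.02, "03:01": 0.06, "03:02": 0.06, "04:01": 0.02,
                   "04:04": 0.03, "07:01": 0.13, "08:04": 0.06, "09:01": 0.05,
                   "11:01": 0.05, "11:02": 0.03, "12:01": 0.06, "13:01": 0.05,
                   "13:02": 0.07, "15:01": 0.06, "15:03": 0.11}, "99:99"),
    "DQA1": _norm({"01:01": 0.05, "01:02": 0.30, "01:03": 0.03, "01:05": 0.05,
                   "02:01": 0.12, "03:01": 0.05, "03:03": 0.08, "04:01": 0.10,
                   "05:01": 0.08, "05:05": 0.13}, "99:99"),
    "DQB1": _norm({"02:01": 0.08, "02:02": 0.15, "03:01": 0.09, "03:02": 0.07,
                   "03:03": 0.02, "03:19": 0.06, "04:02": 0.08, "05:01": 0.14,
                   "06:02": 0.19, "06:03": 0.03}, "99:99"),
}

#: the planted disease model of the study-like default: the protective and
#: susceptible pocket-1 combinations at their reported odds ratios
STUDY_EFFECTS: tuple[tuple[str, float], ...] = (
    ("a31:M + b84:G|V", math.log(0.57)),
    ("a31:Q + b84:D", math.log(1.63)),
)

GAD_MISSINGNESS = {"DRB1": 1 - 803 / 849, "DPA1": 1 - 783 / 849,
                   "DPB1": 1 - 784 / 849, "DQA1": 1 - 782 / 849,
                   "DQB1": 1 - 774 / 849}


def gad_like_config(effects: Sequence[tuple[str, float]] | None = None,
                    seed: int | None = None) -> GeneratorConfig:
    """The packaged study-like default: 849 subjects, 54.6% cases, two
    self-described-race strata (weights 0.592/0.371 renormalized), DPA1~DPB1
    haplotype tables matched to the common-allele frequency profile with
    remainder mass on a pseudo-allele, per-gene missingness matched to the
    study's per-gene Ns, and the pocket-1 effects planted by default.

    Pass ``effects=[]`` for a null cohort or a custom list to replant.
    """
    w_white, w_black = 0.592, 0.371
    total = w_white + w_black
    cfg = GeneratorConfig(
        n_subjects=849,
        case_fraction=0.546,
        strata=[("White", w_white / total), ("Black", w_black / total)],
        dp_haplotypes={"White": _WHITE_DP, "Black": _BLACK_DP},
        allele_freqs={"White": _WHITE_AF, "Black": _BLACK_AF},
        effects=list(STUDY_EFFECTS if effects is None else effects),
        missingness=dict(GAD_MISSINGNESS),
        seed=seed,
    )
    cfg.baseline_log_odds = baseline_for_case_fraction(cfg)
    return cfg


def dpb1_universe_config(n_subjects: int = 400) -> GeneratorConfig:
    """A single-stratum null cohort putting positive frequency on every DPB1
    allele in the packaged expression map (paired uniformly with the four
    mapped DPA1 alleles), for LD analyses that need the whole allele
    universe represented."""
    dpb1 = sorted(a.name for a in default_expression_map().entries)
    dpa1 = ("01:03", "02:01", "02:02", "03:01")
    haps = {(dpa1[i % len(dpa1)], b): 1.0 for i, b in enumerate(dpb1)}
    total = len(haps)
    haps = {k: 1.0 / total for k in haps}
    return GeneratorConfig(
        n_subjects=n_subjects, case_fraction=0.5, strata=[("all", 1.0)],
        dp_haplotypes={"all": haps}, allele_freqs={"all": {}})


def pooled_dp_haplotypes(config: GeneratorConfig) -> dict[tuple[str, str], float]:
    """Stratum-weighted DPA1~DPB1 haplotype frequencies of a config."""
    pooled: dict[tuple[str, str], float] = {}
    for label, w in config.strata:
        for hap, f in config.dp_haplotypes[label].items():
            pooled[hap] = pooled.get(hap, 0.0) + w * f
    return pooled


# --- YAML config I/O -------------------------------------------------------

def config_to_yaml(config: GeneratorConfig, path: str | Path) -> None:
    doc = {
        "n_subjects": config.n_subjects,
        "case_fraction": config.case_fraction,
        "strata": [[l, w] for l, w in config.strata],
        "dp_haplotypes": {label: {f"{a}~{b}": f for (a, b), f in tab.items()}
                          for label, tab in config.dp_haplotypes.items()},
        "allele_freqs": config.allele_freqs,
        "effects": [[f, b] for f, b in config.effects],
        "baseline_log_odds": config.baseline_log_odds,
        "missingness": config.missingness,
        "seed": config.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    dp = {label: {tuple(k.split("~")): float(v) for k, v in tab.items()}
          for label, tab in doc["dp_haplotypes"].items()}
    return GeneratorConfig(
        n_subjects=int(doc["n_subjects"]),
        case_fraction=float(doc["case_fraction"]),
        strata=[(l, float(w)) for l, w in doc["strata"]],
        dp_haplotypes=dp,
        allele_freqs=doc.get("allele_freqs", {}),
        effects=[(f, float(b)) for f, b in doc.get("effects", [])],
        baseline_log_odds=float(doc.get("baseline_log_odds", 0.0)),
        missingness=doc.get("missingness", {}),
        seed=doc.get("seed"),
    )
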