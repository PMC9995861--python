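"""Two-locus EM haplotype-frequency estimation for unphased genotypes
(DPA1~DPB1, DQA1~DQB1) with per-haplotype chi-squared association testing.

The model: each subject carries two A1~B1 haplotypes drawn independently
(HWE). An unphased double-heterozygote is compatible with two phase
configurations; the E-step weighs each configuration by the product of the
current haplotype frequencies and the M-step re-estimates frequencies from
expected chromosome counts. The log-likelihood is asserted non-decreasing at
every iteration. Initialization is the product of marginal allele
frequencies, so the fit is deterministic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .association import Z95
from .cohort import CASE, GenotypeTable
from .registry import Allele

Haplotype = tuple[Allele, Allele]  # (A1 allele, B1 allele)
Config = tuple[Haplotype, Haplotype]  # unordered pair of haplotypes


class EMError(ValueError):
    pass


@dataclass
class HaplotypeFrequencyEstimate:
    haplotypes: list[Haplotype]
    freqs: np.ndarray
    loglik: float
    loglik_trace: list[float]
    posteriors: dict[str, list[tuple[Config, float]]]
    n_iter: int
    converged: bool
    n_subjects: int

    def freq_of(self, hap: Haplotype) -> float:
        try:
            return float(self.freqs[self.haplotypes.index(hap)])
        except ValueError:
            return 0.0

    def as_dict(self) -> dict[Haplotype, float]:
        return {h: float(f) for h, f in zip(self.haplotypes, self.freqs)}


@dataclass
class HaplotypeAssociation:
    haplotype: Haplotype | str  # "binned" for the rare-haplotype bin
    case_count: float
    control_count: float
    case_total: float
    control_total: float
    or_: float
    ci95: tuple[float, float]
    p: float
    flags: set[str] = field(default_factory=set)


def _genotype_class(pair_a: tuple[Allele, Allele],
                    pair_b: tuple[Allele, Allele]) -> tuple:
    return (tuple(sorted(pair_a)), tuple(sorted(pair_b)))


def _class_configs(key: tuple) -> list[tuple[Haplotype, Haplotype]]:
    (a1, a2), (b1, b2) = key
    cfgs = [((a1, b1), (a2, b2))]
    if a1 != a2 and b1 != b2:
        alt = ((a1, b2), (a2, b1))
        cfgs.append(alt)
    return cfgs


def em_fit(table: GenotypeTable, gene_a: str, gene_b: str,
           tol: float = 1e-8, max_iter: int = 1000,
           seed: int | None = None) -> HaplotypeFrequencyEstimate:
    """EM over unphased two-locus genotypes.

    Runs until the log-likelihood changes by less than *tol* or *max_iter*
    iterations. *seed* is accepted for interface stability but unused: the
    deterministic marginal-product initialization needs no restarts.
    """
    subjects = [s for s in table.subjects
                if gene_a in s.genotypes and gene_b in s.genotypes]
    if not subjects:
        raise EMError(f"no subjects typed at both {gene_a} and {gene_b}")

    class_of: dict[tuple, int] = {}
    class_counts: list[int] = []
    subj_class: list[int] = []
    for s in subjects:
        key = _genotype_class(s.genotypes[gene_a], s.genotypes[gene_b])
        if key not in class_of:
            class_of[key] = len(class_counts)
            class_counts.append(0)
        class_counts[class_of[key]] += 1
        subj_class.append(class_of[key])
    keys = list(class_of)
    n_class = len(keys)
    counts = np.asarray(class_counts, dtype=float)
    n = len(subjects)

    hap_index: dict[Haplotype, int] = {}
    cfg_h1, cfg_h2, cfg_class, cfg_mult = [], [], [], []
    class_cfgs: list[list[Config]] = []
    for ci, key in enumerate(keys):
        cfgs = _class_configs(key)
        class_cfgs.append(cfgs)
        for (h1, h2) in cfgs:
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            cfg_h1.append(hap_index[h1])
            cfg_h2.append(hap_index[h2])
            cfg_class.append(ci)
            cfg_mult.append(1.0 if h1 == h2 else 2.0)
    haplotypes = sorted(hap_index, key=hap_index.get)  # type: ignore[arg-type]
    h1a = np.asarray(cfg_h1)
    h2a = np.asarray(cfg_h2)
    cls = np.asarray(cfg_class)
    mult = np.asarray(cfg_mult)
    n_hap = len(haplotypes)

    # marginal-product start, restricted to observed (compatible) haplotypes
    pa: dict[Allele, float] = {}
    pb: dict[Allele, float] = {}
    for s in subjects:
        for a in s.genotypes[gene_a]:
            pa[a] = pa.get(a, 0.0) + 1.0
        for b in s.genotypes[gene_b]:
            pb[b] = pb.get(b, 0.0) + 1.0
    f = np.array([pa[h[0]] * pb[h[1]] for h in haplotypes])
    f /= f.sum()

    def e_step(freqs: np.ndarray):
        w = mult * freqs[h1a] * freqs[h2a]
        denom = np.zeros(n_class)
        np.add.at(denom, cls, w)
        if np.any(denom <= 0):
            # a class with zero mass under current freqs: spread uniformly
            bad = denom <= 0
            w = np.where(bad[cls], mult, w)
            denom = np.zeros(n_class)
            np.add.at(denom, cls, w)
        post = w / denom[cls]
        ll = float(np.sum(counts * np.log(denom)))
        return post, ll

    def m_step(post: np.ndarray) -> np.ndarray:
        expected = np.zeros(n_hap)
        np.add.at(expected, h1a, counts[cls] * post)
        np.add.at(expected, h2a, counts[cls] * post)
        return expected / (2.0 * n)

    trace: list[float] = []
    prev_ll = -math.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        post, ll = e_step(f)
        if ll < prev_ll - 1e-9 * max(1.0, abs(ll)):
            raise EMError(f"log-likelihood decreased: {prev_ll} -> {ll}")
        trace.append(ll)
        f = m_step(post)
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    # one final E+M so that stored posteriors and frequencies are mutually
    # consistent (expected combo dosages then sum exactly to 2n * freq mass)
    post, ll = e_step(f)
    trace.append(ll)
    f = m_step(post)

    cfg_post_by_class: list[list[float]] = [[] for _ in range(n_class)]
    for p_val, ci in zip(post, cls):
        cfg_post_by_class[ci].append(float(p_val))
    posteriors = {}
    for s, ci in zip(subjects, subj_class):
        posteriors[s.subject_id] = list(zip(class_cfgs[ci], cfg_post_by_class[ci]))

    return HaplotypeFrequencyEstimate(
        haplotypes=haplotypes, freqs=f, loglik=float(trace[-1]),
        loglik_trace=trace, posteriors=posteriors, n_iter=n_iter,
        converged=converged, n_subjects=n)


def direct_counting_frequencies(table: GenotypeTable, gene_a: str,
                                gene_b: str) -> dict[Haplotype, float]:
    """EM-free haplotype coding: phase-unambiguous subjects (at most one
    locus heterozygous) are counted directly; a double-heterozygote's two
    possible phasings each get half weight. The sensitivity check for the
    EM route."""
    counts: dict[Haplotype, float] = {}
    informative = 0
    for s in table.subjects:
        if gene_a not in s.genotypes or gene_b not in s.genotypes:
            continue
        informative += 1
        key = _genotype_class(s.genotypes[gene_a], s.genotypes[gene_b])
        cfgs = _class_configs(key)
        w = 1.0 / len(cfgs)
        for cfg in cfgs:
            for h in cfg:
                counts[h] = counts.get(h, 0.0) + w
    if informative == 0:
        raise EMError("no informative subjects")
    total = sum(counts.values())
    return {h: c / total for h, c in counts.items()}


def expected_counts_by_status(est: HaplotypeFrequencyEstimate,
                              statuses: Mapping[str, str]) -> tuple[
                                  dict[Haplotype, float], dict[Haplotype, float],
                                  float, float]:
    """EM-expected chromosome counts of each haplotype in cases/controls."""
    case_counts: dict[Haplotype, float] = {h: 0.0 for h in est.haplotypes}
    ctrl_counts: dict[Haplotype, float] = {h: 0.0 for h in est.haplotypes}
    n_case = n_ctrl = 0
    for sid, cfgs in est.posteriors.items():
        is_case = statuses[sid] == CASE
        target = case_counts if is_case else ctrl_counts
        if is_case:
            n_case += 1
        else:
            n_ctrl += 1
        for (h1, h2), p in cfgs:
            target[h1] += p
            target[h2] += p
    return case_counts, ctrl_counts, 2.0 * n_case, 2.0 * n_ctrl


def two_by_two_association(case_count: float, control_count: float,
                           case_total: float, control_total: float,
                           label: Haplotype | str = "") -> HaplotypeAssociation:
    """OR with Woolf (log) 95% CI and 1-df Pearson chi-squared p for a
    haplotype-vs-rest by case-vs-control 2x2 of chromosome counts."""
    a, b = case_count, case_total - case_count
    c, d = control_count, control_total - control_count
    flags: set[str] = set()
    if min(a, b, c, d) <= 0:
        flags.add("separation")
        or_ = math.inf if (a > 0 and c == 0) or b == 0 else 0.0
        return HaplotypeAssociation(label, a, c, case_total, control_total,
                                    or_, (math.nan, math.nan), math.nan, flags)
    or_ = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    if se > 50:
        flags.add("unstable")
        return HaplotypeAssociation(label, a, c, case_total, control_total,
                                    or_, (math.nan, math.nan), math.nan, flags)
    ci = (or_ * math.exp(-Z95 * se), or_ * math.exp(Z95 * se))
    obs = np.array([[a, b], [c, d]])
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / obs.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return HaplotypeAssociation(label, a, c, case_total, control_total,
                                or_, ci, p, flags)


def haplotype_test(est: HaplotypeFrequencyEstimate,
                   statuses: Mapping[str, str],
                   min_expected: float = 5.0) -> list[HaplotypeAssociation]:
    """Per-haplotype 2x2 chi-squared tests on EM-expected chromosome counts.

    Haplotypes with an expected count below *min_expected* in either group
    are merged into a single "binned" pseudo-haplotype before testing.
    """
    case_counts, ctrl_counts, n_case, n_ctrl = expected_counts_by_status(
        est, statuses)
    results = []
    binned_case = binned_ctrl = 0.0
    n_binned = 0
    for h in est.haplotypes:
        if case_counts[h] + ctrl_counts[h] < 1e-6:
            continue  # numerically absent (posterior dust), nothing to bin
        if case_counts[h] < min_expected or ctrl_counts[h] < min_expected:
            binned_case += case_counts[h]
            binned_ctrl += ctrl_counts[h]
            n_binned += 1
        else:
            results.append(two_by_two_association(
                case_counts[h], ctrl_counts[h], n_case, n_ctrl, h))
    if n_binned == len(est.haplotypes):
        raise EMError("all haplotypes fell below the binning threshold")
    if n_binned:
        results.append(two_by_two_association(
            binned_case, binned_ctrl, n_case, n_ctrl, "binned"))
    return results


def status_map(table: GenotypeTable) -> dict[str, str]:
    return {s.subject_id: s.status for s in table.subjects}
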