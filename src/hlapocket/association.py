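"""Frequency estimation, additive-model logistic association, Bonferroni
families and binary-feature correlation.

Odds ratios come from unadjusted logistic fits of case/control status on a
per-subject dosage (0/1/2 copies of an allele/residue/combination, or an
expected dosage in [0, 2] for phase-ambiguous features). Confidence intervals
and p-values are Wald; complete or quasi-complete separation is reported as a
flagged result (infinite or zero OR, missing CI) rather than an exception.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class FrequencyEstimate:
    feature: str
    count: float
    total: int
    freq: float
    ci95: tuple[float, float]


@dataclass
class AssociationResult:
    feature: str
    or_: float
    ci95: tuple[float, float]
    p: float
    n_subjects: int
    flags: set[str] = field(default_factory=set)

    @property
    def log_or(self) -> float:
        return math.log(self.or_) if 0 < self.or_ < math.inf else math.copysign(
            math.inf, self.or_ - 1)


@dataclass(frozen=True)
class CorrectionFamily:
    m: int
    alpha_family: float = 0.05

    @property
    def threshold(self) -> float:
        return self.alpha_family / self.m


def bonferroni(m: int, alpha: float = 0.05) -> CorrectionFamily:
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return CorrectionFamily(m, alpha)


def frequency(count: float, total: int, feature: str = "") -> FrequencyEstimate:
    """Chromosome-count frequency with a Wald 95% CI clipped to [0, 1]."""
    if total <= 0:
        raise ValueError("total chromosomes must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    p = count / total
    half = Z95 * math.sqrt(p * (1.0 - p) / total)
    return FrequencyEstimate(feature, count, total, p,
                             (max(0.0, p - half), min(1.0, p + half)))


def frequency_filter(freqs_by_scope: Mapping[str, Mapping[str, float]],
                     threshold: float = 0.05) -> list[str]:
    """Retain a feature if its frequency is >= *threshold* in ANY scope
    (full cohort or either stratum) — the disjunctive common-allele rule."""
    features: set[str] = set()
    for scope in freqs_by_scope.values():
        features.update(scope)
    kept = [f for f in sorted(features)
            if any(scope.get(f, 0.0) >= threshold
                   for scope in freqs_by_scope.values())]
    return kept


def _separation(dosage: np.ndarray, status: np.ndarray) -> str | None:
    """Detect (quasi-)complete separation for a scalar dosage."""
    d1, d0 = dosage[status == 1], dosage[status == 0]
    if d1.min() >= d0.max():
        return "separation" if d1.min() > d0.max() else "quasi-separation"
    if d1.max() <= d0.min():
        return "separation" if d1.max() < d0.min() else "quasi-separation"
    return None


def fit_additive(dosage: Sequence[float], status: Sequence[int],
                 feature: str = "") -> AssociationResult:
    """Additive-model logistic regression of case status on dosage.

    OR = exp(slope) per dosage unit, Wald 95% CI and two-sided p. A constant
    dosage is an error; separated data yield a flagged result with an
    infinite (or zero) OR and no CI.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(status, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("dosage and status must be equal-length 1-d vectors")
    if len(np.unique(y)) < 2:
        raise ValueError("both phenotype classes must be present")
    if np.ptp(d) == 0:
        raise ValueError(f"constant dosage for feature {feature!r}")
    sep = _separation(d, y)
    if sep == "separation":
        direction = math.inf if d[y == 1].mean() > d[y == 0].mean() else 0.0
        return AssociationResult(feature, direction, (math.nan, math.nan),
                                 math.nan, len(d), {"separation"})
    X = sm.add_constant(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100, method="newton", tol=1e-10)
    slope, se = float(fit.params[1]), float(fit.bse[1])
    flags: set[str] = set()
    if sep == "quasi-separation" or not np.isfinite(se) or se > 50:
        flags.add("unstable")
    if not fit.mle_retvals.get("converged", True):
        flags.add("unstable")
    if not np.isfinite(slope) or abs(slope) > 30:
        # numerically separated despite the range check (e.g. fractional
        # expected dosages): report a flagged boundary estimate
        direction = math.inf if slope > 0 else 0.0
        return AssociationResult(feature, direction, (math.nan, math.nan),
                                 math.nan, len(d), flags | {"separation"})
    with np.errstate(over="ignore"):
        or_ = float(np.exp(slope))
        ci = (float(np.exp(slope - Z95 * se)), float(np.exp(slope + Z95 * se)))
    p = 2.0 * stats.norm.sf(abs(slope) / se) if se > 0 else math.nan
    return AssociationResult(feature, or_, ci, p, len(d), flags)


def binary_correlation(x: Iterable[int], y: Iterable[int]) -> float:
    """Pearson correlation (phi) between two binary indicator vectors."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors must have equal length")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(xa, ya)[0, 1])


def association_table(results: Iterable[AssociationResult],
                      family: CorrectionFamily | None = None) -> list[dict]:
    """Rows mirroring the allele-association table layout (feature, OR, CI,
    p, flags, and significance under the family threshold if given)."""
    rows = []
    for r in results:
        row = {"feature": r.feature, "or": r.or_, "ci_low": r.ci95[0],
               "ci_high": r.ci95[1], "p": r.p, "n": r.n_subjects,
               "flags": ",".join(sorted(r.flags))}
        if family is not None:
            row["significant"] = bool(np.isfinite(r.p) and r.p < family.threshold)
        rows.append(row)
    return rows
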