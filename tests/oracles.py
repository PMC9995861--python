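"""Independent oracles, written before and kept independent of the package
code paths they check.

- ``logistic_slope_oracle``: plain Newton iteration on the logistic
  log-likelihood for intercept+slope, no statsmodels.
- ``haplotype_ml_oracle``: direct maximization of the unphased two-locus
  likelihood over the frequency simplex (softmax parametrization, multiple
  starts), no EM.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def logistic_slope_oracle(dosage, status, tol=1e-12, max_iter=200):
    """ML (intercept, slope) for logit P(y=1) = b0 + b1*d by Newton."""
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(status, dtype=float)
    X = np.column_stack([np.ones_like(d), d])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _configs(pair_a, pair_b):
    (a1, a2), (b1, b2) = sorted(pair_a), sorted(pair_b)
    cfgs = [((a1, b1), (a2, b2))]
    if a1 != a2 and b1 != b2:
        cfgs.append(((a1, b2), (a2, b1)))
    return cfgs


def haplotype_ml_oracle(genotypes, n_starts=8, seed=0):
    """Maximize the two-locus genotype likelihood directly.

    *genotypes* is a list of (pair_a, pair_b) unordered allele pairs. Returns
    {haplotype: ML frequency}. Suitable for small instances only (the
    parameter space is the full simplex over compatible haplotypes).
    """
    haps: list = []
    index: dict = {}
    subj_cfgs = []
    for pa, pb in genotypes:
        cfgs = []
        for h1, h2 in _configs(tuple(pa), tuple(pb)):
            for h in (h1, h2):
                if h not in index:
                    index[h] = len(haps)
                    haps.append(h)
            mult = 1.0 if h1 == h2 else 2.0
            cfgs.append((index[h1], index[h2], mult))
        subj_cfgs.append(cfgs)
    k = len(haps)

    def neg_loglik(z):
        z = np.concatenate([[0.0], z])
        f = np.exp(z - z.max())
        f /= f.sum()
        ll = 0.0
        for cfgs in subj_cfgs:
            lik = sum(m * f[i] * f[j] for i, j, m in cfgs)
            ll += np.log(max(lik, 1e-300))
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        z0 = np.zeros(k - 1) if s == 0 else rng.normal(scale=1.5, size=k - 1)
        res = minimize(neg_loglik, z0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10,
                                "fatol": 1e-12})
        res = minimize(neg_loglik, res.x, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    z = np.concatenate([[0.0], best.x])
    f = np.exp(z - z.max())
    f /= f.sum()
    return {h: float(f[index[h]]) for h in haps}
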