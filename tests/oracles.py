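"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written from the definitions, not from the package's
implementation paths: exhaustive greedy selection for clumping, the literal
step-up scan for BH, and full configuration enumeration for colocalization.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_clump(snps, chroms, positions, pvals, r2_lookup,
                      p_threshold, r2_threshold, window_bp):
    """Literal greedy clumping by repeated scanning (no vectorization)."""
    items = [
        {"snp": s, "chrom": c, "pos": int(b), "p": float(p)}
        for s, c, b, p in zip(snps, chroms, positions, pvals)
        if p < p_threshold
    ]
    leads = []
    while items:
        best = min(items, key=lambda it: (it["p"], it["chrom"], it["pos"]))
        leads.append(best["snp"])
        remaining = []
        for it in items:
            if it is best:
                continue
            if (it["chrom"] == best["chrom"]
                    and abs(it["pos"] - best["pos"]) <= window_bp
                    and r2_lookup(it["snp"], best["snp"]) >= r2_threshold):
                continue
            remaining.append(it)
        items = remaining
    return leads


def brute_force_bh(pvals):
    """Step-up BH by the definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[i] = min(1.0, min(candidates))
    return np.array(q)


def _log_abf(beta, se, w):
    v = se ** 2
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(v / (v + w)) + z2 * w / (v + w))


def enumerate_coloc(beta1, se1, beta2, se2, p1, p2, p12, w1, w2):
    """Exact enumeration over all single-SNP and SNP-pair causal configurations.

    Works in plain floating point on small |z| regions, and in log space via
    per-hypothesis logsumexp otherwise; returns the normalized pp0..pp4 and
    the unnormalized log posteriors for log-scale comparisons.
    """
    from scipy.special import logsumexp

    m = len(beta1)
    la = np.array([_log_abf(beta1[j], se1[j], w1) for j in range(m)])
    lb = np.array([_log_abf(beta2[j], se2[j], w2) for j in range(m)])

    lp = np.empty(5)
    lp[0] = 0.0
    lp[1] = np.log(p1) + logsumexp(la)
    lp[2] = np.log(p2) + logsumexp(lb)
    pairs = [la[i] + lb[j] for i, j in itertools.product(range(m), range(m)) if i != j]
    lp[3] = (np.log(p1) + np.log(p2) + logsumexp(pairs)) if pairs else -np.inf
    lp[4] = np.log(p12) + logsumexp([la[j] + lb[j] for j in range(m)])
    pp = np.exp(lp - logsumexp(lp))
    return pp, lp


def weighted_median_reference(ratios, weights):
    """Definition-level weighted median: cumulative midpoints + interpolation."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2
    below = np.where(s < 0.5)[0]
    if len(below) == 0:
        return r[0]
    k = below[-1]
    if k == len(r) - 1:
        return r[-1]
    return r[k] + (r[k + 1] - r[k]) * (0.5 - s[k]) / (s[k + 1] - s[k])
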