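"""Enumeration colocalization under one causal variant per trait.

For a region of m shared variants, five hypotheses are compared: H0 neither
trait associated; H1/H2 only trait 1/2; H3 both, distinct causal variants;
H4 both, one shared causal variant. With per-SNP Wakefield ABFs for each
trait the (relative) hypothesis likelihoods are

    L1 = sum_j ABF1_j          L2 = sum_j ABF2_j
    L4 = sum_j ABF1_j ABF2_j   L3 = sum_{i != j} ABF1_i ABF2_j = L1 L2 - L4

weighted by the per-SNP priors p1, p2, p12 into unnormalized posteriors
(1, p1 L1, p2 L2, p1 p2 L3, p12 L4). All sums are log-space; the L3
expansion falls back to a direct pairwise loop when L1*L2 and L4 nearly
cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .finemap import PRIOR_SD_BINARY, PRIOR_SD_QUANT, wakefield_log_abf

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
COLOC_PP4_THRESHOLD = 0.8
_L3_FALLBACK_MAX_SNPS = 2000


@dataclass
class ColocResult:
    region_id: str
    n_snps: int
    priors: tuple[float, float, float]
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def _log_L3(labf1: np.ndarray, labf2: np.ndarray,
            l1: float, l2: float, l4: float) -> float:
    """log sum_{i != j} ABF1_i ABF2_j, guarding the L1*L2 - L4 cancellation."""
    total, diag = l1 + l2, l4
    if total - diag > 0.1:
        # safe: log(e^total - e^diag) = total + log1p(-e^(diag-total))
        return total + np.log1p(-np.exp(diag - total))
    if len(labf1) <= _L3_FALLBACK_MAX_SNPS:
        cross = labf1[:, None] + labf2[None, :]
        np.fill_diagonal(cross, -np.inf)
        return float(logsumexp(cross))
    raise FloatingPointError(
        "catastrophic cancellation in L3 on a region too large for the "
        "pairwise fallback")


def coloc_abf(trait1_records: pd.DataFrame, trait2_records: pd.DataFrame,
              priors: tuple[float, float, float] = DEFAULT_PRIORS,
              prior_sd1: float = PRIOR_SD_QUANT,
              prior_sd2: float = PRIOR_SD_QUANT,
              region_id: str = "") -> ColocResult:
    """Posterior probabilities PP0-PP4 for one region.

    Both record tables need SNP, BETA, SE; variants are matched on id
    (records must already be harmonized to a shared effect allele — only
    squared z enter the ABFs, so orientation cannot change the result, but
    the variant *sets* must overlap). ``prior_sd2`` defaults to the
    quantitative prior; pass ``PRIOR_SD_BINARY`` (0.2) for a disease trait.
    """
    p1, p2, p12 = priors
    if p1 <= 0 or p2 <= 0 or p12 <= 0:
        raise ValueError("priors must be positive")
    t1 = trait1_records.set_index("SNP")
    t2 = trait2_records.set_index("SNP")
    shared = t1.index.intersection(t2.index)
    if len(shared) == 0:
        raise ValueError("no shared variants in the region")
    labf1 = wakefield_log_abf(t1.loc[shared, "BETA"].to_numpy(),
                              t1.loc[shared, "SE"].to_numpy(), prior_sd1)
    labf2 = wakefield_log_abf(t2.loc[shared, "BETA"].to_numpy(),
                              t2.loc[shared, "SE"].to_numpy(), prior_sd2)
    l1 = float(logsumexp(labf1))
    l2 = float(logsumexp(labf2))
    l4 = float(logsumexp(labf1 + labf2))
    l3 = _log_L3(labf1, labf2, l1, l2, l4)
    log_post = np.array([
        0.0,
        np.log(p1) + l1,
        np.log(p2) + l2,
        np.log(p1) + np.log(p2) + l3,
        np.log(p12) + l4,
    ])
    pp = np.exp(log_post - logsumexp(log_post))
    return ColocResult(region_id=region_id, n_snps=len(shared),
                       priors=(p1, p2, p12), pp0=float(pp[0]), pp1=float(pp[1]),
                       pp2=float(pp[2]), pp3=float(pp[3]), pp4=float(pp[4]))


def coloc_call(result: ColocResult,
               threshold: float = COLOC_PP4_THRESHOLD) -> tuple[bool, dict]:
    """Colocalized iff PP4 > threshold (strict). Sub-threshold PP4 values are
    still reported numerically in the returned row."""
    colocalized = result.pp4 > threshold
    row = {"region": result.region_id, "nsnps": result.n_snps,
           "pp0": result.pp0, "pp1": result.pp1, "pp2": result.pp2,
           "pp3": result.pp3, "pp4": result.pp4,
           "threshold": threshold, "colocalized": colocalized}
    return colocalized, row
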