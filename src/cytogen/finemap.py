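"""Single-causal-variant Bayesian fine-mapping via Wakefield's approximate
Bayes factor.

This is deliberately *not* a multi-effect (SuSiE-style) mapper: each locus is
assumed to carry exactly one causal variant with a flat prior over variants,
the per-variant evidence is Wakefield's ABF

    log ABF = 1/2 [ log(V / (V + W)) + z^2 * W / (V + W) ]

with V = se^2, W the prior effect variance, and posterior inclusion
probabilities are the normalized ABFs. The 95% credible set is the minimal
descending-PIP prefix whose cumulative probability reaches the coverage
target. Loci carrying several independent signals will see their credible
sets concentrate on the strongest one; that limitation is inherent to the
model, not a bug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: prior SD of the standardized effect for quantitative traits
PRIOR_SD_QUANT = 0.15
#: prior SD for log-odds effects of binary traits
PRIOR_SD_BINARY = 0.2


def wakefield_log_abf(beta, se, prior_sd: float = PRIOR_SD_QUANT):
    """Log approximate Bayes factor for association, larger = more associated.

    Vectorized over beta/se. ``prior_sd`` is the prior SD (W = prior_sd^2).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    W = float(prior_sd) ** 2
    if W <= 0:
        raise ValueError("prior variance must be positive")
    V = se ** 2
    z2 = (beta / se) ** 2
    shrink = W / (V + W)
    return 0.5 * (np.log(V / (V + W)) + z2 * shrink)


@dataclass
class CredibleSet:
    locus_id: str
    variant_ids: list[str]       # all locus variants, PIP-descending
    pips: np.ndarray             # aligned with variant_ids
    coverage_target: float
    n_set: int                   # size of the credible set (prefix length)
    contains_lead: bool

    @property
    def set_variant_ids(self) -> list[str]:
        return self.variant_ids[:self.n_set]

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.pips)

    @property
    def achieved_coverage(self) -> float:
        return float(self.cumulative[self.n_set - 1])


def credible_set(locus_records: pd.DataFrame, prior_sd: float = PRIOR_SD_QUANT,
                 coverage: float = 0.95, locus_id: str = "",
                 lead_variant_id: str | None = None) -> CredibleSet:
    """PIPs and the minimal credible set for one locus.

    ``locus_records`` needs columns SNP, BP, BETA, SE (e.g. a meta table
    restricted to the locus, with BETA_HAT/SE_HAT renamed). PIPs are the
    log-space-normalized Wakefield ABFs under the single-causal-variant
    assumption; ties in PIP order break by position ascending.
    """
    if len(locus_records) == 0:
        raise ValueError("credible_set needs at least one variant")
    labf = wakefield_log_abf(locus_records["BETA"].to_numpy(),
                             locus_records["SE"].to_numpy(), prior_sd)
    pips = np.exp(labf - logsumexp(labf))
    order = np.lexsort((locus_records["BP"].to_numpy(), -pips))
    ids = locus_records["SNP"].to_numpy()[order].tolist()
    pips_sorted = pips[order]
    cum = np.cumsum(pips_sorted)
    n_set = int(np.searchsorted(cum, coverage - 1e-12) + 1)
    n_set = min(n_set, len(ids))
    lead = lead_variant_id if lead_variant_id is not None else ids[0]
    return CredibleSet(locus_id=locus_id, variant_ids=ids, pips=pips_sorted,
                       coverage_target=coverage, n_set=n_set,
                       contains_lead=lead in ids[:n_set])


def credible_set_table(cs: CredibleSet) -> pd.DataFrame:
    cum = cs.cumulative
    return pd.DataFrame({
        "locus_id": cs.locus_id,
        "variant_id": cs.variant_ids,
        "pip": cs.pips,
        "cumulative": cum,
        "in_credible_set": [i < cs.n_set for i in range(len(cs.variant_ids))],
        "contains_lead": cs.contains_lead,
    })
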