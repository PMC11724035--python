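"""LD-score regression: SNP-heritability and cross-trait genetic correlation.

Univariate model: E[chi2_j] = 1 + n h2 l_j / M with l_j the LD score
(sum of r^2 of variant j with every variant in its block, self term
included). Cross-trait: E[z1_j z2_j] = sqrt(n1 n2) rho_g l_j / M +
intercept, where the free intercept absorbs sample overlap (zero by
construction in the synthetic cohorts). Both are one-pass weighted
least-squares fits with 1/l_j heteroskedasticity weights — a deliberate
desk-scale simplification of the reference tool's iterative weighting —
and delete-a-block jackknife standard errors over position-contiguous
variant blocks.

Weighting is a two-pass scheme: an initial 1/l fit provides a slope guess,
then exactly one reweighting iteration with the model-implied variance
weights (for chi2, w_j = 1/[2 l_j (1 + n h2 l_j / M)^2]; the cross-trait
analogue for z1 z2) — no iteration to convergence. On LD references whose
scores barely vary (a single AR(1) profile) the slope is weakly identified
and estimates are noisy regardless of weighting; references with
heterogeneous LD across blocks are the intended regime.

Genetic correlation rg = rho_g / sqrt(h2_1 h2_2) is only defined for
positive heritabilities: a non-positive h2 estimate yields an explicit
``undefined_h2`` status with a missing rg rather than a crash (the gray
cells of a correlation heatmap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth_gwas import LDMatrix, LDReference


def ld_scores(ld: LDMatrix | LDReference) -> np.ndarray:
    """Per-variant LD scores l_j = sum_k r2_jk within the block (self term in)."""
    blocks = ld.blocks if isinstance(ld, LDReference) else [ld]
    return np.concatenate([blk.r2().sum(axis=1) for blk in blocks])


def _wls(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted LS of y on (1, x); returns (intercept, slope)."""
    sw = np.sum(w)
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    if sxx <= 0 or np.max(x) == np.min(x):
        raise ValueError("degenerate design: LD scores are constant")
    slope = np.sum(w * (x - mx) * (y - my)) / sxx
    return my - slope * mx, slope


def _jackknife(values: np.ndarray) -> float:
    """Delete-one-block jackknife SE from the B leave-one-out estimates."""
    b = len(values)
    return float(np.sqrt((b - 1) / b * np.sum((values - values.mean()) ** 2)))


def _block_slices(m: int, n_blocks: int) -> list[np.ndarray]:
    return [idx for idx in np.array_split(np.arange(m), n_blocks) if len(idx)]


@dataclass
class LDSCResult:
    trait1: str
    trait2: str | None
    h2_1: float
    h2_1_se: float
    intercept_1: float
    h2_2: float | None = None
    h2_2_se: float | None = None
    intercept_2: float | None = None
    gencov: float | None = None
    gencov_se: float | None = None
    cross_intercept: float | None = None
    rg: float | None = None
    rg_se: float | None = None
    status: str = "ok"          # ok | undefined_h2
    rg_flagged: bool = False    # |rg| > 1.25


def _h2_weights(x: np.ndarray, ell: np.ndarray, h2_guess: float) -> np.ndarray:
    g = min(max(h2_guess, 0.0), 1.0)
    return 1.0 / (2.0 * ell * (1.0 + g * x) ** 2)


def h2_regression(z, n, ell, m_variants: int | None = None,
                  n_blocks: int = 20) -> tuple[float, float, float, float]:
    """Fit chi2 on LD score; returns (h2, h2_se, intercept, intercept_se)."""
    z = np.asarray(z, dtype=float)
    ell = np.asarray(ell, dtype=float)
    n_arr = np.broadcast_to(np.asarray(n, dtype=float), z.shape)
    if len(z) < 200:
        raise ValueError("h2_regression needs at least 200 variants")
    m = m_variants if m_variants is not None else len(z)
    chi2 = z ** 2
    x = n_arr * ell / m

    _, slope0 = _wls(chi2, x, 1.0 / ell)
    w = _h2_weights(x, ell, slope0)
    icept, slope = _wls(chi2, x, w)
    h2 = slope
    blocks = _block_slices(len(z), n_blocks)
    if len(blocks) < 2:
        raise ValueError("need at least 2 jackknife blocks")
    h2_jk, ic_jk = [], []
    for idx in blocks:
        keep = np.ones(len(z), dtype=bool)
        keep[idx] = False
        ic_b, sl_b = _wls(chi2[keep], x[keep], w[keep])
        h2_jk.append(sl_b)
        ic_jk.append(ic_b)
    return (float(h2), _jackknife(np.array(h2_jk)),
            float(icept), _jackknife(np.array(ic_jk)))


def rg_regression(z1, z2, n1, n2, ell, m_variants: int | None = None,
                  n_blocks: int = 20, trait1: str = "trait1",
                  trait2: str = "trait2") -> LDSCResult:
    """Cross-trait LDSC on a shared variant set.

    z1 and z2 must be aligned to the same variants (and the same effect
    allele); mismatched lengths are an error.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("traits must share an aligned variant set")
    ell = np.asarray(ell, dtype=float)
    m = m_variants if m_variants is not None else len(z1)

    h2_1, h2_1_se, ic1, _ = h2_regression(z1, n1, ell, m, n_blocks)
    h2_2, h2_2_se, ic2, _ = h2_regression(z2, n2, ell, m, n_blocks)

    x = np.sqrt(float(n1) * float(n2)) * ell / m
    y = z1 * z2
    icept0, slope0 = _wls(y, x, 1.0 / ell)
    # one reweighting pass with the model-implied variance of z1*z2
    w = 1.0 / (ell * ((1.0 + max(h2_1, 0.0) * float(n1) * ell / m)
                      * (1.0 + max(h2_2, 0.0) * float(n2) * ell / m)
                      + (slope0 * x + icept0) ** 2))
    cross_icept, gencov = _wls(y, x, w)
    blocks = _block_slices(len(z1), n_blocks)
    gc_jk = []
    for idx in blocks:
        keep = np.ones(len(z1), dtype=bool)
        keep[idx] = False
        _, sl_b = _wls(y[keep], x[keep], w[keep])
        gc_jk.append(sl_b)
    gencov_se = _jackknife(np.array(gc_jk))

    result = LDSCResult(trait1=trait1, trait2=trait2,
                        h2_1=h2_1, h2_1_se=h2_1_se, intercept_1=ic1,
                        h2_2=h2_2, h2_2_se=h2_2_se, intercept_2=ic2,
                        gencov=float(gencov), gencov_se=gencov_se,
                        cross_intercept=float(cross_icept))
    if h2_1 <= 0 or h2_2 <= 0:
        result.status = "undefined_h2"
        return result
    denom = np.sqrt(h2_1 * h2_2)
    result.rg = float(gencov / denom)
    # rg jackknife: re-derive h2 per left-out block for a consistent ratio
    rg_jk = []
    for idx in blocks:
        keep = np.ones(len(z1), dtype=bool)
        keep[idx] = False
        xk, wk = x[keep], w[keep]
        n_arr1 = np.broadcast_to(np.asarray(n1, dtype=float), z1.shape)[keep]
        n_arr2 = np.broadcast_to(np.asarray(n2, dtype=float), z2.shape)[keep]
        ellk = ell[keep]
        _, h1b = _wls(z1[keep] ** 2, n_arr1 * ellk / m, wk)
        _, h2b = _wls(z2[keep] ** 2, n_arr2 * ellk / m, wk)
        _, gcb = _wls(y[keep], xk, wk)
        if h1b > 0 and h2b > 0:
            rg_jk.append(gcb / np.sqrt(h1b * h2b))
    if len(rg_jk) >= 2:
        result.rg_se = _jackknife(np.array(rg_jk))
    result.rg_flagged = abs(result.rg) > 1.25
    return result
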