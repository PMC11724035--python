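"""Two-sample Mendelian randomization with cis instruments.

Instruments for a cytokine are variants within +/-300 kb of its encoding
gene, associated at p < 5e-5 and clumped at r2 < 0.1 (r2 < 0.01 for
eQTL-expression exposures). The primary estimator is fixed-effects
inverse-variance-weighted MR; MR-Egger regression (free intercept capturing
directional pleiotropy, t-based inference on n-2 df) and the weighted median
(robust to <50% invalid weight) are sensitivity analyses. Steiger filtering
drops instruments with a stronger (larger |beta|) association with the
outcome than the exposure. Multiple testing is controlled per analysis
family with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import loci as loci_mod
from .sumstats_io import SummaryStatSet, harmonize_pair
from .synth_gwas import LDReference

logger = logging.getLogger("cytogen")

CIS_FLANK_BP = 300_000
INSTRUMENT_P_CUT = 5e-5
INSTRUMENT_R2_CUT = 0.1
EQTL_R2_CUT = 0.01

_MIN_NSNP = {"wald": 1, "ivw_fe": 2, "egger": 3, "weighted_median": 3}


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_fdr: float | None = None

    def odds_ratio_ci(self) -> tuple[float, float, float]:
        """(OR, lower, upper) per SD of exposure for binary outcomes."""
        return (float(np.exp(self.beta)),
                float(np.exp(self.beta - 1.959963984540054 * self.se)),
                float(np.exp(self.beta + 1.959963984540054 * self.se)))


# ---------------------------------------------------------------------------
# Instrument selection
# ---------------------------------------------------------------------------

def select_cis_instruments(exposure_records: pd.DataFrame,
                           gene_window: tuple[str, int, int],
                           ld: LDReference, flank_bp: int = CIS_FLANK_BP,
                           p_cut: float = INSTRUMENT_P_CUT,
                           r2_cut: float = INSTRUMENT_R2_CUT) -> list[str]:
    """Cis instrument ids for one exposure: window filter -> p < p_cut
    (strict) -> greedy clump at r2_cut.

    ``exposure_records`` needs SNP, CHR, BP, P columns (1-based positions);
    ``gene_window`` is 1-based inclusive. An empty result is returned (and
    logged), never raised — the pair is skipped downstream.
    """
    chrom, start, end = gene_window
    df = exposure_records
    in_window = ((df["CHR"].astype(str) == str(chrom))
                 & (df["BP"] >= start - flank_bp) & (df["BP"] <= end + flank_bp))
    window = df.loc[in_window, ["SNP", "CHR", "BP", "P"]]
    leads = loci_mod.clump(window, ld, p_threshold=p_cut, r2_threshold=r2_cut,
                           window_bp=2 * flank_bp + (end - start))
    if not leads:
        logger.info("select_cis_instruments: no instruments in %s:%d-%d at p<%g",
                    chrom, start, end, p_cut)
    return leads


def steiger_filter(harmonized: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop rows whose outcome association is stronger than the exposure's:
    |beta_y| > |beta_x| (strict; equality keeps the row). Returns
    (kept rows, dropped variant ids). Assumes both betas standardized.
    """
    drop = harmonized["beta_y"].abs() > harmonized["beta_x"].abs()
    dropped = harmonized.loc[drop, "SNP"].tolist()
    return harmonized.loc[~drop].copy(), dropped


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def wald_ratio(beta_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-instrument ratio estimate with the first-order SE se_y/|beta_x|."""
    if beta_x == 0:
        raise ValueError("wald ratio undefined for beta_x = 0")
    beta = beta_y / beta_x
    se = se_y / abs(beta_x)
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return MREstimate(method="wald", beta=float(beta), se=float(se),
                      pvalue=float(p), n_snp=1)


def ivw_fixed(harmonized: pd.DataFrame) -> MREstimate:
    """Fixed-effects IVW: beta = sum(bx by / sy^2) / sum(bx^2 / sy^2),
    se = 1/sqrt(sum(bx^2/sy^2)). Falls back to the Wald ratio for a single
    instrument (logged)."""
    bx = harmonized["beta_x"].to_numpy(float)
    by = harmonized["beta_y"].to_numpy(float)
    sy = harmonized["se_y"].to_numpy(float)
    if len(bx) == 0:
        raise ValueError("no instruments")
    if len(bx) == 1:
        logger.info("ivw_fixed: single instrument, falling back to Wald ratio")
        est = wald_ratio(bx[0], by[0], sy[0])
        return est
    w = bx ** 2 / sy ** 2
    beta = float(np.sum(bx * by / sy ** 2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MREstimate(method="ivw_fe", beta=beta, se=se, pvalue=p, n_snp=len(bx))


def egger(harmonized: pd.DataFrame) -> MREstimate | None:
    """MR-Egger: WLS of beta_y on beta_x with weights 1/se_y^2 and a free
    intercept, rows first oriented so beta_x >= 0. Slope = causal estimate,
    intercept = directional pleiotropy; p-values from t with n-2 df.
    Returns None for fewer than 3 instruments."""
    if len(harmonized) < 3:
        return None
    flip = np.sign(harmonized["beta_x"].to_numpy(float))
    flip[flip == 0] = 1.0
    bx = harmonized["beta_x"].to_numpy(float) * flip
    by = harmonized["beta_y"].to_numpy(float) * flip
    sy = harmonized["se_y"].to_numpy(float)
    w = 1.0 / sy ** 2
    sw = np.sum(w)
    mx, my = np.sum(w * bx) / sw, np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    if sxx <= 0:
        return None
    slope = np.sum(w * (bx - mx) * (by - my)) / sxx
    icept = my - slope * mx
    df_resid = len(bx) - 2
    resid = by - icept - slope * bx
    sigma2 = np.sum(w * resid ** 2) / df_resid if df_resid > 0 else np.nan
    se_slope = np.sqrt(sigma2 / sxx)
    se_icept = np.sqrt(sigma2 * (1.0 / sw + mx ** 2 / sxx))
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), df_resid)
    p_icept = 2.0 * stats.t.sf(abs(icept / se_icept), df_resid)
    return MREstimate(method="egger", beta=float(slope), se=float(se_slope),
                      pvalue=float(p_slope), n_snp=len(bx),
                      egger_intercept=float(icept), intercept_se=float(se_icept),
                      intercept_p=float(p_icept))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated median: order values, take cumulative midpoints
    s_j = cum(w)_j - w_j/2 (weights normalized), linearly interpolate to 0.5."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, v))


def weighted_median(harmonized: pd.DataFrame, n_boot: int = 200,
                    seed: int = 0) -> MREstimate | None:
    """Weighted-median MR with inverse-variance ratio weights
    w_j = beta_xj^2 / se_yj^2 and a seeded parametric bootstrap SE.
    Returns None for fewer than 3 instruments."""
    if len(harmonized) < 3:
        return None
    bx = harmonized["beta_x"].to_numpy(float)
    by = harmonized["beta_y"].to_numpy(float)
    sx = harmonized["se_x"].to_numpy(float)
    sy = harmonized["se_y"].to_numpy(float)
    ratios = by / bx
    weights = bx ** 2 / sy ** 2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(len(bx))
        byb = by + sy * rng.standard_normal(len(by))
        ok = bxb != 0
        boots[b] = _weighted_median(byb[ok] / bxb[ok], bxb[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else (0.0 if beta else 1.0)
    return MREstimate(method="weighted_median", beta=beta, se=se,
                      pvalue=float(p), n_snp=len(bx))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values:
    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Assembled analyses
# ---------------------------------------------------------------------------

def _run_pair(harmonized: pd.DataFrame, exposure_id: str, outcome_id: str,
              wm_seed: int) -> list[dict]:
    rows = []
    base = {"exposure": exposure_id, "outcome": outcome_id}
    if len(harmonized) == 0:
        return rows
    if len(harmonized) == 1:
        r = harmonized.iloc[0]
        if r["beta_x"] == 0:
            return rows
        est = wald_ratio(r["beta_x"], r["beta_y"], r["se_y"])
        rows.append({**base, "method": est.method, "nsnp": 1, "beta": est.beta,
                     "se": est.se, "p": est.pvalue})
        return rows
    est = ivw_fixed(harmonized)
    rows.append({**base, "method": est.method, "nsnp": est.n_snp,
                 "beta": est.beta, "se": est.se, "p": est.pvalue})
    eg = egger(harmonized)
    if eg is not None:
        rows.append({**base, "method": "egger", "nsnp": eg.n_snp,
                     "beta": eg.beta, "se": eg.se, "p": eg.pvalue,
                     "egger_intercept": eg.egger_intercept,
                     "egger_intercept_p": eg.intercept_p})
    wm = weighted_median(harmonized, seed=wm_seed)
    if wm is not None:
        rows.append({**base, "method": "weighted_median", "nsnp": wm.n_snp,
                     "beta": wm.beta, "se": wm.se, "p": wm.pvalue})
    return rows


_EDGE_COLUMNS = ["exposure", "outcome", "method", "nsnp", "beta", "se", "p",
                 "q", "egger_intercept", "egger_intercept_p",
                 "steiger_dropped", "het_dropped", "status"]


def _finalize_family(rows: list[dict], skips: list[dict],
                     fdr_method: str = "ivw") -> pd.DataFrame:
    """Attach BH q-values across the primary (IVW/Wald) estimates of a family
    and the directional-concordance flags of the sensitivity estimates."""
    df = pd.DataFrame(rows)
    out = pd.concat([df, pd.DataFrame(skips)], ignore_index=True) if skips else df
    for col in _EDGE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    if "status" in out.columns:
        out["status"] = out["status"].fillna("ok")
    primary = out["method"].isin(["ivw_fe", "wald"])
    if primary.any():
        # p underflows to 0 for extreme z; floor before the step-up
        p_prim = np.clip(out.loc[primary, "p"].to_numpy(float), 1e-300, 1.0)
        out.loc[primary, "q"] = bh_fdr(p_prim)
    # directional concordance of each sensitivity estimate with its pair's primary
    prim_sign = out.loc[primary].set_index(["exposure", "outcome"])["beta"]
    conc = []
    for _, r in out.iterrows():
        if r["method"] in ("egger", "weighted_median") and (r["exposure"], r["outcome"]) in prim_sign.index:
            conc.append(bool(np.sign(r["beta"]) == np.sign(prim_sign[(r["exposure"], r["outcome"])])))
        else:
            conc.append(np.nan)
    out["concordant_with_primary"] = conc
    return out[_EDGE_COLUMNS + ["concordant_with_primary"]]


def mr_network(meta_results: dict[str, pd.DataFrame],
               meta_sets: dict[str, SummaryStatSet],
               gene_windows: dict[str, tuple[str, int, int]],
               ld: LDReference, flank_bp: int = CIS_FLANK_BP,
               p_cut: float = INSTRUMENT_P_CUT, r2_cut: float = INSTRUMENT_R2_CUT,
               het_exclude: bool = False, het_p_cut: float = 0.05,
               wm_seed: int = 2024) -> pd.DataFrame:
    """Cytokine -> cytokine causal network over every ordered pair.

    For each exposure != outcome: select cis instruments for the exposure,
    drop any variant that is also in the *outcome's own* cis instrument list
    (no variant may instrument both sides), harmonize, Steiger-filter,
    optionally drop heterogeneous variants (meta HetPval < ``het_p_cut``),
    then run IVW + Egger + weighted median. BH-FDR runs across the primary
    estimates of all tested pairs.
    """
    cytokines = [c for c in meta_results if c in gene_windows]
    instruments = {c: select_cis_instruments(
        meta_results[c].rename(columns={"P_META": "P"}), gene_windows[c], ld,
        flank_bp, p_cut, r2_cut) for c in cytokines}
    rows, skips = [], []
    for exp_id in cytokines:
        for out_id in cytokines:
            if exp_id == out_id:
                continue
            ids = [v for v in instruments[exp_id] if v not in set(instruments[out_id])]
            if not ids:
                skips.append({"exposure": exp_id, "outcome": out_id,
                              "status": "no_instruments"})
                continue
            exp_meta = meta_results[exp_id]
            exp_sub = exp_meta[exp_meta["SNP"].isin(ids)]
            if het_exclude:
                exp_sub = exp_sub[~(exp_sub["HET_P"] < het_p_cut)]
            if exp_sub.empty:
                skips.append({"exposure": exp_id, "outcome": out_id,
                              "status": "no_instruments"})
                continue
            from .meta import meta_to_sumstats
            exp_set = meta_to_sumstats(exp_sub, exp_id)
            try:
                harm = harmonize_pair(exp_set, meta_sets[out_id])
            except ValueError:
                skips.append({"exposure": exp_id, "outcome": out_id,
                              "status": "no_overlap"})
                continue
            harm, steiger_dropped = steiger_filter(harm)
            if harm.empty:
                skips.append({"exposure": exp_id, "outcome": out_id,
                              "status": "all_steiger_dropped"})
                continue
            pair_rows = _run_pair(harm, exp_id, out_id, wm_seed)
            for r in pair_rows:
                r["steiger_dropped"] = len(steiger_dropped)
            rows.extend(pair_rows)
    if not rows and not skips:
        return pd.DataFrame(columns=_EDGE_COLUMNS + ["concordant_with_primary"])
    return _finalize_family(rows, skips)


def disease_screen(meta_results: dict[str, pd.DataFrame],
                   disease_sets: dict[str, SummaryStatSet],
                   gene_windows: dict[str, tuple[str, int, int]],
                   ld: LDReference, flank_bp: int = CIS_FLANK_BP,
                   p_cut: float = INSTRUMENT_P_CUT,
                   r2_cut: float = INSTRUMENT_R2_CUT,
                   het_exclude: bool = False, het_p_cut: float = 0.05,
                   wm_seed: int = 2024) -> pd.DataFrame:
    """Cytokine x disease cis-MR screen; outcomes on the log-odds scale.

    One BH-FDR family across all cytokine x disease primary estimates
    (global family; a per-disease family is a caller-side groupby). Effects
    are emitted both as log-OR (beta) and as OR per SD with a 95% CI.
    """
    from .meta import meta_to_sumstats

    rows, skips = [], []
    for cyt, meta_df in meta_results.items():
        if cyt not in gene_windows:
            continue
        ids = select_cis_instruments(
            meta_df.rename(columns={"P_META": "P"}), gene_windows[cyt], ld,
            flank_bp, p_cut, r2_cut)
        sub = meta_df[meta_df["SNP"].isin(ids)]
        if het_exclude:
            sub = sub[~(sub["HET_P"] < het_p_cut)]
        for dis, dset in disease_sets.items():
            if sub.empty:
                skips.append({"exposure": cyt, "outcome": dis,
                              "status": "no_instruments"})
                continue
            try:
                harm = harmonize_pair(meta_to_sumstats(sub, cyt), dset)
            except ValueError:
                skips.append({"exposure": cyt, "outcome": dis,
                              "status": "no_overlap"})
                continue
            pair_rows = _run_pair(harm, cyt, dis, wm_seed)
            rows.extend(pair_rows)
    if not rows and not skips:
        return pd.DataFrame(columns=_EDGE_COLUMNS + ["concordant_with_primary"])
    out = _finalize_family(rows, skips)
    est = out["method"].isin(["ivw_fe", "wald", "egger", "weighted_median"])
    out.loc[est, "odds_ratio"] = np.exp(out.loc[est, "beta"])
    out.loc[est, "or_ci_low"] = np.exp(out.loc[est, "beta"] - 1.959963984540054 * out.loc[est, "se"])
    out.loc[est, "or_ci_high"] = np.exp(out.loc[est, "beta"] + 1.959963984540054 * out.loc[est, "se"])
    return out


def twas_mr(eqtl_sets: dict[str, SummaryStatSet],
            outcome_sets: dict[str, SummaryStatSet],
            gene_windows: dict[str, tuple[str, int, int]],
            ld: LDReference, flank_bp: int = CIS_FLANK_BP,
            p_cut: float = INSTRUMENT_P_CUT, r2_cut: float = EQTL_R2_CUT,
            wm_seed: int = 2024) -> pd.DataFrame:
    """Transcriptome-wide MR: cis-eQTL gene-expression exposures (clumped at
    the stricter r2 < 0.01) against each outcome trait."""
    rows, skips = [], []
    for gene, eset in eqtl_sets.items():
        if gene not in gene_windows:
            continue
        ids = select_cis_instruments(eset.records, gene_windows[gene], ld,
                                     flank_bp, p_cut, r2_cut)
        sub = eset.records[eset.records["SNP"].isin(ids)]
        for out_id, oset in outcome_sets.items():
            if sub.empty:
                skips.append({"exposure": gene, "outcome": out_id,
                              "status": "no_instruments"})
                continue
            exp_set = SummaryStatSet(trait_id=gene, cohort_id=eset.cohort_id,
                                     records=sub.reset_index(drop=True))
            try:
                harm = harmonize_pair(exp_set, oset)
            except ValueError:
                skips.append({"exposure": gene, "outcome": out_id,
                              "status": "no_overlap"})
                continue
            rows.extend(_run_pair(harm, gene, out_id, wm_seed))
    if not rows and not skips:
        return pd.DataFrame(columns=_EDGE_COLUMNS + ["concordant_with_primary"])
    return _finalize_family(rows, skips)
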