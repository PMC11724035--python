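"""Fixed-effects sample-size-weighted z-score meta-analysis across cohorts.

Per-cohort signed z statistics are combined with weights sqrt(N) (the METAL
SAMPLESIZE scheme), because the three source assays report effects on
incompatible scales. Standardized betas are reconstructed afterwards from
z, effect-allele frequency and total N; Cochran's Q heterogeneity is
computed on the per-cohort *reconstructed* standardized betas, which puts
all assays on one scale first.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import SummaryStatSet

logger = logging.getLogger("cytogen")

GENOME_WIDE_P = 5e-8

#: median of the chi-square distribution with 1 df, the null median of z^2
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def meta_sample_size(z_per_cohort, n_per_cohort):
    """Combine per-cohort z with weights w_i = sqrt(n_i).

    Missing cohorts (NaN z) contribute '?' to the direction string and are
    excluded from the sums. Returns (z_meta, p_meta, direction, n_total);
    all-missing input returns (nan, nan, '?'*k, 0) so callers can omit the
    variant.
    """
    z = np.asarray(z_per_cohort, dtype=float)
    n = np.asarray(n_per_cohort, dtype=float)
    present = np.isfinite(z)
    if np.any(n[present] <= 0):
        raise ValueError("sample sizes must be positive")
    direction = "".join(
        "?" if not ok else ("+" if zi > 0 else "-" if zi < 0 else "0")
        for ok, zi in zip(present, z))
    if not present.any():
        return float("nan"), float("nan"), direction, 0.0
    w = np.sqrt(n[present])
    z_meta = float(np.sum(w * z[present]) / np.sqrt(np.sum(w ** 2)))
    p_meta = float(2.0 * stats.norm.sf(abs(z_meta)))
    return z_meta, p_meta, direction, float(np.sum(n[present]))


def reconstruct_beta_se(z_meta, eaf, n_total):
    """Standardized beta and SE from z, frequency f and N:
    beta = z / sqrt(2 f (1-f) (N + z^2)), se = 1 / sqrt(2 f (1-f) (N + z^2)).
    """
    z = np.asarray(z_meta, dtype=float)
    f = np.asarray(eaf, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("eaf must be strictly inside (0, 1)")
    if np.any(n <= 0):
        raise ValueError("n_total must be positive")
    denom = np.sqrt(2.0 * f * (1.0 - f) * (n + z ** 2))
    return z / denom, 1.0 / denom


def cochran_q(betas, ses):
    """Cochran's Q over k >= 2 cohorts' (reconstructed) betas; p on k-1 df.

    With fewer than two non-missing cohorts Q is undefined: returns
    (nan, nan). Non-positive SEs are an error.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    keep = np.isfinite(b) & np.isfinite(s)
    if np.any(s[keep] <= 0):
        raise ValueError("standard errors must be positive")
    k = int(keep.sum())
    if k < 2:
        return float("nan"), float("nan")
    w = 1.0 / s[keep] ** 2
    b_fe = np.sum(w * b[keep]) / np.sum(w)
    q = float(np.sum(w * (b[keep] - b_fe) ** 2))
    het_p = float(stats.chi2.sf(q, k - 1))
    return q, het_p


def genomic_lambda(p_values) -> float:
    """Genomic inflation: median observed chi2(1) over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        warnings.warn(f"genomic_lambda computed from only {len(p)} p-values",
                      stacklevel=2)
    chi2 = stats.norm.isf(p / 2.0) ** 2
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def explained_variance(lead_variants) -> float:
    """Total trait variance explained by independent lead variants:
    sum of 2 f (1-f) beta^2 over (eaf, beta_hat) pairs; empty set -> 0.
    """
    total = 0.0
    for f, beta in lead_variants:
        total += 2.0 * f * (1.0 - f) * beta ** 2
    return total


def meta_analyze(cohort_sets: dict[str, SummaryStatSet],
                 cohort_order: list[str] | None = None,
                 trait_id: str | None = None) -> pd.DataFrame:
    """Meta-analyze one trait across cohorts into the MetaResult table.

    Variants present in any cohort are retained; those in a single cohort
    keep k_cohorts = 1 (flagged by the direction string and k column) and a
    missing Q. Heterogeneity uses per-cohort betas reconstructed from each
    cohort's own z, EAF and N.

    Output columns: SNP CHR BP EA OA EAF Z_META P_META BETA_HAT SE_HAT
    N_TOTAL K_COHORTS DIRECTION Q HET_P.
    """
    if cohort_order is None:
        cohort_order = list(cohort_sets)
    missing = set(cohort_sets) - set(cohort_order)
    if missing:
        raise ValueError(f"cohorts not in cohort_order: {sorted(missing)}")

    frames = {}
    for cohort in cohort_order:
        if cohort in cohort_sets:
            frames[cohort] = cohort_sets[cohort].records.set_index("SNP")
    if not frames:
        raise ValueError("no cohorts supplied")
    all_snps = pd.Index([])
    for df in frames.values():
        all_snps = all_snps.union(df.index)

    k = len(cohort_order)
    zmat = np.full((len(all_snps), k), np.nan)
    nmat = np.full((len(all_snps), k), np.nan)
    bmat = np.full((len(all_snps), k), np.nan)  # reconstructed per-cohort betas
    smat = np.full((len(all_snps), k), np.nan)
    meta_eaf = np.full(len(all_snps), np.nan)
    info = {}
    for ci, cohort in enumerate(cohort_order):
        if cohort not in frames:
            continue
        df = frames[cohort].reindex(all_snps)
        ok = df["Z"].notna().to_numpy()
        zmat[ok, ci] = df["Z"].to_numpy(float)[ok]
        nmat[ok, ci] = df["N"].to_numpy(float)[ok]
        b, s = reconstruct_beta_se(df["Z"].to_numpy(float)[ok],
                                   df["EAF"].to_numpy(float)[ok],
                                   df["N"].to_numpy(float)[ok])
        bmat[ok, ci] = b
        smat[ok, ci] = s
        take = ok & ~np.isfinite(meta_eaf)
        meta_eaf[take] = df["EAF"].to_numpy(float)[take]
        for col in ("CHR", "BP", "EA", "OA"):
            prev = info.setdefault(col, pd.Series(index=all_snps, dtype=object))
            fill = prev.isna() & df[col].notna()
            prev[fill] = df[col][fill]

    rows = []
    for i, snp in enumerate(all_snps):
        z_meta, p_meta, direction, n_total = meta_sample_size(zmat[i], nmat[i])
        if not np.isfinite(z_meta):
            continue
        beta_hat, se_hat = reconstruct_beta_se(z_meta, meta_eaf[i], n_total)
        q, het_p = cochran_q(bmat[i], smat[i])
        rows.append({
            "SNP": snp, "CHR": info["CHR"][snp], "BP": int(info["BP"][snp]),
            "EA": info["EA"][snp], "OA": info["OA"][snp], "EAF": meta_eaf[i],
            "Z_META": z_meta, "P_META": p_meta,
            "BETA_HAT": float(beta_hat), "SE_HAT": float(se_hat),
            "N_TOTAL": n_total, "K_COHORTS": int(np.isfinite(zmat[i]).sum()),
            "DIRECTION": direction, "Q": q, "HET_P": het_p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    if trait_id is not None:
        out.insert(0, "TRAIT", trait_id)
    return out


def meta_to_sumstats(meta_df: pd.DataFrame, trait_id: str,
                     trait_type: str = "quantitative") -> SummaryStatSet:
    """View a meta-analysis table as a SummaryStatSet (for MR/coloc reuse)."""
    rec = pd.DataFrame({
        "SNP": meta_df["SNP"], "CHR": meta_df["CHR"], "BP": meta_df["BP"],
        "EA": meta_df["EA"], "OA": meta_df["OA"], "EAF": meta_df["EAF"],
        "BETA": meta_df["BETA_HAT"], "SE": meta_df["SE_HAT"],
        "P": meta_df["P_META"], "N": meta_df["N_TOTAL"], "Z": meta_df["Z_META"],
    })
    return SummaryStatSet(trait_id=trait_id, cohort_id="meta", records=rec,
                          trait_type=trait_type)
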