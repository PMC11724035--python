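"""Greedy LD clumping, independent-locus calling, cis/trans labels, replication.

The locus definition follows the two-stage convention used for pQTL atlases:
genome-wide significant variants are clumped greedily at a strict r2
threshold (default 0.001) within a +/-1 Mb window, then clump leads closer
than 1 Mb on the same chromosome are chained into one independent locus. A
locus is *cis* for a trait when its lead lies within +/-300 kb of the
trait's encoding gene, else *trans*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth_gwas import LDReference

logger = logging.getLogger("cytogen")

CIS_FLANK_BP = 300_000
LOCUS_SEPARATION_BP = 1_000_000


@dataclass
class Locus:
    locus_id: str
    chrom: str
    lead_variant_id: str
    lead_p: float
    member_variant_ids: list[str]
    span: tuple[int, int]
    trait_id: str = ""
    label: str | None = None  # "cis" | "trans" | None (no gene window known)


def clump(records: pd.DataFrame, ld: LDReference, p_threshold: float = 5e-8,
          r2_threshold: float = 0.001, window_bp: int = 1_000_000) -> list[str]:
    """Greedy clumping of significant variants; returns lead ids in pick order.

    Repeatedly take the smallest-p unassigned variant with p < p_threshold as
    a lead and absorb all unassigned variants within ``window_bp`` whose r2
    with it is >= ``r2_threshold``. Ties on p break by (chrom, pos)
    ascending. Variants absent from the LD reference are excluded (count
    logged).
    """
    df = records.loc[records["P"] < p_threshold,
                     ["SNP", "CHR", "BP", "P"]].copy()
    known = df["SNP"].map(lambda v: v in ld)
    n_missing = int((~known).sum())
    if n_missing:
        logger.info("clump: %d significant variants absent from the LD reference",
                    n_missing)
        df = df[known]
    if df.empty:
        return []
    df = df.sort_values(["P", "CHR", "BP"], kind="mergesort").reset_index(drop=True)

    unassigned = df
    leads: list[str] = []
    while len(unassigned):
        lead = unassigned.iloc[0]
        leads.append(lead["SNP"])
        same_window = ((unassigned["CHR"] == lead["CHR"])
                       & ((unassigned["BP"] - lead["BP"]).abs() <= window_bp))
        r2 = unassigned.loc[same_window, "SNP"].map(
            lambda v: ld.r2_pair(v, lead["SNP"]))
        absorbed = same_window.copy()
        absorbed[same_window] = (r2 >= r2_threshold).to_numpy()
        absorbed.iloc[0] = True  # the lead itself
        unassigned = unassigned[~absorbed]
    return leads


def merge_to_loci(leads: pd.DataFrame,
                  min_separation_bp: int = LOCUS_SEPARATION_BP,
                  trait_id: str = "") -> list[Locus]:
    """Chain clump leads into independent loci.

    ``leads`` needs columns SNP, CHR, BP, P. Consecutive same-chromosome
    leads separated by <= ``min_separation_bp`` join the same locus
    (transitive chaining); the locus lead is its smallest-p member.
    """
    df = leads.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    loci: list[Locus] = []
    if df.empty:
        return loci
    new_group = (df["CHR"] != df["CHR"].shift()) | \
                (df["BP"] - df["BP"].shift() > min_separation_bp)
    group_id = new_group.cumsum()
    for gi, grp in df.groupby(group_id):
        best = grp.loc[grp["P"].idxmin()]
        loci.append(Locus(
            locus_id=f"{trait_id + '_' if trait_id else ''}locus_{len(loci) + 1:03d}",
            chrom=str(best["CHR"]), lead_variant_id=best["SNP"],
            lead_p=float(best["P"]), member_variant_ids=list(grp["SNP"]),
            span=(int(grp["BP"].min()), int(grp["BP"].max())),
            trait_id=trait_id))
    return loci


def classify_cis_trans(locus: Locus, gene_window: tuple[str, int, int] | None,
                       lead_pos: int, flank_bp: int = CIS_FLANK_BP) -> str | None:
    """cis iff the lead lies within [start - flank, end + flank] (closed) on
    the gene's chromosome; trans otherwise; None when no gene window exists.
    ``gene_window`` is 1-based inclusive (chrom, start, end)."""
    if gene_window is None:
        logger.info("classify_cis_trans: no gene window for trait %s; label missing",
                    locus.trait_id)
        return None
    chrom, start, end = gene_window
    if str(locus.chrom) == str(chrom) and start - flank_bp <= lead_pos <= end + flank_bp:
        return "cis"
    return "trans"


def call_loci(meta_df: pd.DataFrame, ld: LDReference,
              gene_window: tuple[str, int, int] | None,
              p_threshold: float = 5e-8, r2_threshold: float = 0.001,
              window_bp: int = 1_000_000,
              min_separation_bp: int = LOCUS_SEPARATION_BP,
              flank_bp: int = CIS_FLANK_BP, trait_id: str = "") -> list[Locus]:
    """clump -> merge -> label, for one trait's meta table (columns of meta_analyze)."""
    records = meta_df.rename(columns={"P_META": "P"})[["SNP", "CHR", "BP", "P"]]
    lead_ids = clump(records, ld, p_threshold, r2_threshold, window_bp)
    leads = records[records["SNP"].isin(lead_ids)]
    loci = merge_to_loci(leads, min_separation_bp, trait_id=trait_id)
    pos = records.set_index("SNP")["BP"]
    for locus in loci:
        locus.label = classify_cis_trans(locus, gene_window,
                                         int(pos[locus.lead_variant_id]), flank_bp)
    return loci


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus_id": lc.locus_id, "trait_id": lc.trait_id, "chrom": lc.chrom,
        "start": lc.span[0], "end": lc.span[1], "lead_variant": lc.lead_variant_id,
        "lead_p": lc.lead_p, "n_members": len(lc.member_variant_ids),
        "members": ";".join(lc.member_variant_ids),
        "label": lc.label if lc.label is not None else ".",
    } for lc in loci], columns=["locus_id", "trait_id", "chrom", "start", "end",
                                "lead_variant", "lead_p", "n_members", "members",
                                "label"])


@dataclass
class ReplicationReport:
    reference_cohort: str
    target_cohort: str
    trait_id: str
    n_significant: int
    n_replicated: int

    @property
    def rate(self) -> float:
        return self.n_replicated / self.n_significant if self.n_significant else float("nan")


def replication_rates(reference, targets: dict[str, object],
                      significant_ids: list[str], rep_p: float = 0.05,
                      drop_missing: bool = True) -> list[ReplicationReport]:
    """Cross-assay replication of one trait's reference-significant variants.

    A reference-significant variant replicates in a target cohort iff it is
    present there, its target p < ``rep_p``, and its effect direction matches
    the reference. With ``drop_missing`` (default) variants absent from the
    target's panel leave the denominator, mirroring availability-filtered
    published comparisons; set False to count them as failures.
    """
    ref = reference.records.set_index("SNP")
    sig = [v for v in significant_ids if v in ref.index]
    reports = []
    for cohort, target in targets.items():
        tgt = target.records.set_index("SNP")
        n_sig = n_rep = 0
        for vid in sig:
            if vid not in tgt.index:
                if not drop_missing:
                    n_sig += 1
                continue
            n_sig += 1
            same_sign = np.sign(tgt.at[vid, "BETA"]) == np.sign(ref.at[vid, "BETA"])
            if tgt.at[vid, "P"] < rep_p and same_sign:
                n_rep += 1
        reports.append(ReplicationReport(
            reference_cohort=reference.cohort_id, target_cohort=cohort,
            trait_id=reference.trait_id, n_significant=n_sig, n_replicated=n_rep))
    return reports


def replication_summary(reports: list[ReplicationReport]) -> pd.DataFrame:
    """Median and IQR of per-trait replication rates for each cohort pair."""
    df = pd.DataFrame([{
        "reference": r.reference_cohort, "target": r.target_cohort,
        "trait_id": r.trait_id, "n_significant": r.n_significant,
        "n_replicated": r.n_replicated, "rate": r.rate,
    } for r in reports])
    if df.empty:
        return df
    summ = (df.dropna(subset=["rate"])
              .groupby(["reference", "target"])["rate"]
              .agg(median="median",
                   q1=lambda s: s.quantile(0.25),
                   q3=lambda s: s.quantile(0.75),
                   n_traits="count")
              .reset_index())
    return summ
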