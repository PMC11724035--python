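"""GWAS summary-statistic containers, TSV readers/writers, validation, harmonization.

The on-disk dialect is a tab-separated file with header
``SNP CHR BP EA OA EAF BETA SE P N [Z]``; ``.`` marks a missing value and
gzipped files are read transparently. Positions are 1-based (GWAS
convention); the gene panel produced by :mod:`cytogen.synth_gwas` is
BED-like 0-based half-open — conversions happen at exactly one boundary
(:func:`gene_window_1based`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cytogen")

GENOME_BUILD = "GRCh37"

#: canonical column order of the sumstats dialect
SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "Z"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


def complement(allele: str) -> str:
    """Reverse-strand complement of an allele string."""
    return "".join(_COMPLEMENT[b] for b in allele)


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be resolved from letters."""
    return len(ea) == 1 and len(oa) == 1 and _COMPLEMENT.get(ea) == oa


@dataclass
class SummaryStatSet:
    """One trait x cohort GWAS.

    ``records`` is a DataFrame in the SUMSTAT_COLUMNS layout, one row per
    variant, variant ids unique.
    """

    trait_id: str
    cohort_id: str
    records: pd.DataFrame
    trait_type: str = "quantitative"  # or "binary"
    genome_build: str = GENOME_BUILD

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.records["SNP"].duplicated().any():
            dupes = self.records.loc[self.records["SNP"].duplicated(), "SNP"].tolist()
            raise ValueError(f"duplicate variant ids in {self.trait_id}/{self.cohort_id}: {dupes[:5]}")

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.records)


def z_from_p(pvalue: float, sign: int) -> float:
    """Signed z from a two-sided p-value: ``sign * Phi^-1(1 - p/2)``.

    ``isf`` evaluates the upper-tail quantile directly, so p down to the
    smallest positive double (~5e-324) maps to a finite z (~38.5); that is
    the numeric floor, below which p must not go (p <= 0 is an error).
    """
    p = float(pvalue)
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p-value must be in (0, 1], got {pvalue}")
    if sign not in (-1, 1):
        raise ValueError(f"sign must be -1 or +1, got {sign}")
    return float(sign * stats.norm.isf(p / 2.0))


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Row-level validation; returns the clean frame and per-reason drop counts."""
    drops: dict[str, int] = {}
    mask = pd.Series(True, index=df.index)

    def flag(cond: pd.Series, reason: str) -> None:
        bad = mask & ~cond
        n = int(bad.sum())
        if n:
            drops[reason] = drops.get(reason, 0) + n
        mask[bad] = False

    ea = df["EA"].astype(str).str.upper()
    oa = df["OA"].astype(str).str.upper()
    df = df.assign(EA=ea, OA=oa)
    flag(ea.map(lambda a: len(a) > 0 and set(a) <= _VALID_ALLELES)
         & oa.map(lambda a: len(a) > 0 and set(a) <= _VALID_ALLELES), "invalid_allele")
    flag(ea != oa, "identical_alleles")
    flag(df["BP"] >= 1, "nonpositive_position")
    flag((df["EAF"] > 0) & (df["EAF"] < 1), "eaf_out_of_range")
    flag(df["SE"] > 0, "nonpositive_se")
    flag((df["P"] > 0) & (df["P"] <= 1), "p_out_of_range")
    flag(df["N"] > 0, "nonpositive_n")

    # beta/se must agree with the p-value-implied |z| where all three are present
    has_all = df["BETA"].notna() & df["SE"].notna() & df["P"].notna()
    z_bs = df["BETA"] / df["SE"]
    with np.errstate(divide="ignore", invalid="ignore"):
        z_p = np.sign(df["BETA"]).replace(0, 1) * stats.norm.isf(df["P"].to_numpy() / 2.0)
    consistent = (~has_all) | ((z_bs - z_p).abs() <= 0.05) | ~np.isfinite(z_p)
    flag(consistent.fillna(True), "z_inconsistent_with_p")

    return df[mask].copy(), drops


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    """Fill derivable columns: Z from beta/se (precedence) else from p, then P/BETA/SE."""
    df = df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z_bs = df["BETA"] / df["SE"]
    m = df["Z"].isna() & z_bs.notna()
    df.loc[m, "Z"] = z_bs[m]
    still = df["Z"].isna() & df["P"].notna() & df["BETA"].notna()
    if still.any():
        df.loc[still, "Z"] = [
            z_from_p(p, 1 if b >= 0 else -1) for p, b in zip(df.loc[still, "P"], df.loc[still, "BETA"])
        ]
    need_p = df["P"].isna() & df["Z"].notna()
    if need_p.any():
        df.loc[need_p, "P"] = 2.0 * stats.norm.sf(np.abs(df.loc[need_p, "Z"].to_numpy(float)))
    return df


def read_sumstats(path, column_map: dict[str, str] | None = None,
                  trait_id: str = "", cohort_id: str = "",
                  trait_type: str = "quantitative") -> SummaryStatSet:
    """Read a sumstats TSV into a :class:`SummaryStatSet`.

    ``column_map`` maps canonical names (SNP, CHR, ...) to the file's header
    names when they differ. Rows failing validation are dropped and the count
    logged; a missing required column or an empty file is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str}, na_values=["."])
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if df.empty:
        raise ValueError(f"empty sumstats file: {path}")
    required = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if "Z" not in df.columns:
        df["Z"] = np.nan
    df = df[SUMSTAT_COLUMNS]
    df = df.astype({"BP": np.int64, "EAF": float, "BETA": float, "SE": float,
                    "P": float, "N": float, "Z": float, "CHR": str, "SNP": str})
    clean, drops = _validate_frame(df)
    n_dropped = sum(drops.values())
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d rows (%s)", path, n_dropped,
                    ", ".join(f"{k}={v}" for k, v in drops.items()))
    clean = _finalize(clean).reset_index(drop=True)
    return SummaryStatSet(trait_id=trait_id or str(path), cohort_id=cohort_id,
                          records=clean, trait_type=trait_type)


def write_sumstats(sset: SummaryStatSet, path) -> None:
    """Write the TSV dialect; missing values become '.'; floats keep 10 sig digits."""
    df = sset.records[SUMSTAT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")


def harmonize_pair(exposure: SummaryStatSet, outcome: SummaryStatSet,
                   palindrome_maf_cut: float = 0.42) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect alleles.

    Variants are joined on variant id. Swapped outcome alleles flip the
    outcome beta sign and mirror its EAF; opposite-strand records are
    recognized by allele complement. Palindromic (A/T, C/G) variants are kept
    only when both sides' MAF < ``palindrome_maf_cut`` and the frequencies
    agree in orientation; every drop is logged with its reason.

    Returns a joined table with columns
    ``SNP CHR BP EA OA eaf_exp eaf_out beta_x se_x p_x n_x beta_y se_y p_y n_y``.
    """
    exp = exposure.records.set_index("SNP")
    out = outcome.records.set_index("SNP")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise ValueError(
            f"no overlapping variants between {exposure.trait_id} and {outcome.trait_id}")

    rows = []
    drops: dict[str, int] = {"palindromic_high_maf": 0, "palindromic_discordant_freq": 0,
                             "allele_mismatch": 0}
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea, oa = e["EA"], e["OA"]
        b_y, f_y = float(o["BETA"]), float(o["EAF"])
        if is_palindromic(ea, oa):
            if (o["EA"], o["OA"]) not in ((ea, oa), (oa, ea)):
                drops["allele_mismatch"] += 1
                continue
            if (o["EA"], o["OA"]) == (oa, ea):
                b_y, f_y = -b_y, 1.0 - f_y
            maf_e = min(e["EAF"], 1 - e["EAF"])
            maf_o = min(f_y, 1 - f_y)
            if maf_e >= palindrome_maf_cut or maf_o >= palindrome_maf_cut:
                drops["palindromic_high_maf"] += 1
                continue
            if (e["EAF"] < 0.5) != (f_y < 0.5):
                drops["palindromic_discordant_freq"] += 1
                continue
        else:
            pair = (o["EA"], o["OA"])
            if pair == (ea, oa):
                pass
            elif pair == (oa, ea):
                b_y, f_y = -b_y, 1.0 - f_y
            elif pair == (complement(ea), complement(oa)):
                pass  # strand flip only
            elif pair == (complement(oa), complement(ea)):
                b_y, f_y = -b_y, 1.0 - f_y
            else:
                drops["allele_mismatch"] += 1
                continue
        rows.append({
            "SNP": snp, "CHR": e["CHR"], "BP": int(e["BP"]), "EA": ea, "OA": oa,
            "eaf_exp": float(e["EAF"]), "eaf_out": f_y,
            "beta_x": float(e["BETA"]), "se_x": float(e["SE"]),
            "p_x": float(e["P"]), "n_x": float(e["N"]),
            "beta_y": b_y, "se_y": float(o["SE"]),
            "p_y": float(o["P"]), "n_y": float(o["N"]),
        })
    dropped = {k: v for k, v in drops.items() if v}
    if dropped:
        logger.info("harmonize_pair(%s, %s): dropped %s", exposure.trait_id,
                    outcome.trait_id, dropped)
    cols = ["SNP", "CHR", "BP", "EA", "OA", "eaf_exp", "eaf_out",
            "beta_x", "se_x", "p_x", "n_x", "beta_y", "se_y", "p_y", "n_y"]
    return pd.DataFrame(rows, columns=cols)


def gene_window_1based(panel_row: pd.Series) -> tuple[str, int, int]:
    """Convert one BED-like gene-panel row (0-based half-open) to a 1-based
    inclusive (chrom, start, end) window."""
    return str(panel_row["chrom"]), int(panel_row["start"]) + 1, int(panel_row["end"])


def read_gene_panel(path) -> pd.DataFrame:
    """Gene panel TSV: chrom, start, end, gene_id, cytokine_id (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start", "end", "gene_id", "cytokine_id"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"gene panel missing column {col!r}")
    return df
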