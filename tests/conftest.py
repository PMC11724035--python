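import numpy as np
import pandas as pd
import pytest

from cytogen import synth_gwas


@pytest.fixture
def ar1_block():
    """A 200-variant AR(1) rho=0.9 LD block on chr1."""
    return synth_gwas.ar1_ld_matrix(200, 0.9, chrom="1", start_pos=1_000_000)


@pytest.fixture
def small_panel_config():
    """A 3-cytokine, 3-cohort panel small enough for per-test simulation."""
    return synth_gwas.SimConfig(
        n_variants=60,
        panel_overlap={
            "CYT1": ["YFS_FINRISK", "SCALLOP", "DECODE"],
            "CYT2": ["YFS_FINRISK", "SCALLOP", "DECODE"],
            "CYT3": ["YFS_FINRISK", "SCALLOP"],
        },
        seed=11,
    )


def make_sumstats(trait_id, cohort_id, snps, betas, ses, eafs=None, ns=None,
                  ea="A", oa="G", chrom="1", positions=None):
    """Hand-built SummaryStatSet for harmonization/MR unit tests."""
    from scipy import stats

    m = len(snps)
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    eafs = np.full(m, 0.3) if eafs is None else np.asarray(eafs, float)
    ns = np.full(m, 10000.0) if ns is None else np.asarray(ns, float)
    ea = [ea] * m if isinstance(ea, str) else list(ea)
    oa = [oa] * m if isinstance(oa, str) else list(oa)
    positions = np.arange(1, m + 1) * 1000 if positions is None else positions
    z = betas / ses
    df = pd.DataFrame({
        "SNP": snps, "CHR": chrom, "BP": positions, "EA": ea, "OA": oa,
        "EAF": eafs, "BETA": betas, "SE": ses,
        "P": 2 * stats.norm.sf(np.abs(z)), "N": ns, "Z": z,
    })
    from cytogen.sumstats_io import SummaryStatSet
    return SummaryStatSet(trait_id=trait_id, cohort_id=cohort_id, records=df)


def single_cohort_meta(sset):
    """View one cohort's sumstats as a meta table (k=1 identity meta)."""
    r = sset.records
    return pd.DataFrame({
        "SNP": r["SNP"], "CHR": r["CHR"], "BP": r["BP"], "EA": r["EA"],
        "OA": r["OA"], "EAF": r["EAF"], "Z_META": r["Z"], "P_META": r["P"],
        "BETA_HAT": r["BETA"], "SE_HAT": r["SE"], "N_TOTAL": r["N"],
        "K_COHORTS": 1, "DIRECTION": "+", "Q": np.nan, "HET_P": np.nan,
    })
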