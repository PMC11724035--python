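"""End-to-end orchestration on synthetic data, with a summary report.

Stages run in a fixed order — simulate, meta, loci, finemap, ldsc,
mr-network, disease screen, coloc, twas, report — and each stage reads only
the previous stages' TSV outputs, so every intermediate is inspectable and
re-derivable. A manifest records the package version, seed, a hash of the
serialized configuration and per-stage row counts; nothing time-dependent is
written, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__, coloc as coloc_mod, finemap, ldsc as ldsc_mod
from . import loci as loci_mod, meta as meta_mod, mr as mr_mod
from . import sumstats_io, synth_gwas

logger = logging.getLogger("cytogen")

STAGES = ["simulate", "meta", "loci", "finemap", "ldsc", "mr_network",
          "disease_screen", "coloc", "twas", "report"]


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.setLevel(getattr(logging, level.upper()))
    if not logger.handlers:
        logger.addHandler(handler)


@dataclass
class PipelineConfig:
    """Thresholds, cohort order, stage toggles and the synthetic-world knobs."""

    seed: int = 1
    n_cytokines: int = 8
    n_diseases: int = 2
    cohort_order: list[str] = field(
        default_factory=lambda: ["YFS_FINRISK", "SCALLOP", "DECODE"])
    sample_sizes: dict[str, int] = field(
        default_factory=lambda: {"YFS_FINRISK": 11000, "SCALLOP": 21000, "DECODE": 35000})
    n_variants_per_gene: int = 200
    ar1_rho: float = 0.9
    cis_effect: float = 0.15
    # network truth: exposure -> (outcome, causal effect per SD)
    causal_links: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("CYT1", "CYT2", 0.4)])
    # disease truth: (cytokine, disease index, log-OR per SD)
    disease_links: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("CYT3", 0, 0.3)])
    n_case: int = 20000
    n_control: int = 180000
    eqtl_n: int = 30000

    gw_p: float = 5e-8
    clump_r2_loci: float = 0.001
    clump_r2_instruments: float = 0.1
    clump_r2_eqtl: float = 0.01
    flank_bp: int = 300_000
    instrument_p: float = 5e-5
    fdr_level: float = 0.05
    coloc_threshold: float = 0.8
    coverage: float = 0.95
    het_exclude: bool = False
    hla_exclusion: tuple[str, int, int] | None = None
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        if not (0 < self.gw_p < 1 and 0 < self.fdr_level < 1
                and 0 < self.coloc_threshold < 1 and 0 < self.coverage <= 1):
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "causal_links" in raw:
            raw["causal_links"] = [tuple(x) for x in raw["causal_links"]]
        if "disease_links" in raw:
            raw["disease_links"] = [tuple(x) for x in raw["disease_links"]]
        if "hla_exclusion" in raw and raw["hla_exclusion"] is not None:
            raw["hla_exclusion"] = tuple(raw["hla_exclusion"])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["causal_links"] = [list(x) for x in d["causal_links"]]
        d["disease_links"] = [list(x) for x in d["disease_links"]]
        if d["hla_exclusion"] is not None:
            d["hla_exclusion"] = list(d["hla_exclusion"])
        return yaml.safe_dump(d, sort_keys=True)

    def sim_config(self) -> synth_gwas.SimConfig:
        cytokines = [f"CYT{i + 1}" for i in range(self.n_cytokines)]
        overlap = {c: list(self.cohort_order) for c in cytokines}
        # the last cytokine, if there are >2, is measured in only two cohorts
        if self.n_cytokines > 2:
            overlap[cytokines[-1]] = list(self.cohort_order[:2])
        trans: dict[str, list[tuple[str, float]]] = {}
        for exp, out, theta in self.causal_links:
            trans.setdefault(out, []).append((exp, theta * self.cis_effect))
        return synth_gwas.SimConfig(
            n_variants=self.n_variants_per_gene, ar1_rho=self.ar1_rho,
            sample_sizes=dict(self.sample_sizes), panel_overlap=overlap,
            seed=self.seed, cis_effect=self.cis_effect, trans_effects=trans,
            disease_params={"theta_true": 0.0, "n_case": self.n_case,
                            "n_control": self.n_control})


def _write(df: pd.DataFrame, path: Path) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")
    return len(df)


def _write_sumstats(sset, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    sumstats_io.write_sumstats(sset, path)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all enabled stages; returns the summary report dict.

    A stage failure raises with the stage name; outputs of completed stages
    are preserved on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    counts: dict[str, int] = {}
    t0 = time.monotonic()

    stage = "simulate"
    try:
        # ---- simulate -----------------------------------------------------
        sim = config.sim_config()
        panel = synth_gwas.simulate_panel(sim)
        cytokines = list(panel.truths)
        for (cyt, cohort), sset in panel.sumstats.items():
            _write_sumstats(sset, out / "sumstats" / f"{cyt}_{cohort}.tsv")
        synth_gwas.write_ld_reference(panel.ld, out / "ld")
        synth_gwas.write_gene_panel(panel.gene_panel, out / "genes.tsv")
        synth_gwas.write_truth_registry(panel.truths, out / "truth.tsv")
        counts["simulate"] = len(panel.sumstats)

        # disease GWAS
        disease_sets: dict[str, sumstats_io.SummaryStatSet] = {}
        dseeds = np.random.SeedSequence(sim.seed).spawn(1000)
        for di in range(config.n_diseases):
            name = f"DIS{di + 1}"
            effects: dict[str, float] = {}
            theta = 0.0
            for cyt, idx, th in config.disease_links:
                if idx == di and cyt in panel.truths:
                    theta = th
                    effects = synth_gwas.marginal_effects(panel.ld, panel.truths[cyt])
            disease_sets[name] = synth_gwas.simulate_disease_gwas(
                panel.ld, effects, theta, config.n_case, config.n_control,
                seed=dseeds[500 + di], eaf=panel.eaf, trait_id=name,
                alleles=panel.alleles)
            _write_sumstats(disease_sets[name], out / "disease" / f"{name}.tsv")
        eqtl_sets = synth_gwas.simulate_eqtl_exposures(
            panel, seed=sim.seed + 7919, n=config.eqtl_n)
        for gene, sset in eqtl_sets.items():
            _write_sumstats(sset, out / "eqtl" / f"{gene}.tsv")

        gene_windows = {
            row["cytokine_id"]: sumstats_io.gene_window_1based(row)
            for _, row in panel.gene_panel.iterrows()}
        gene_windows_by_gene = {
            row["gene_id"]: sumstats_io.gene_window_1based(row)
            for _, row in panel.gene_panel.iterrows()}

        # ---- meta ---------------------------------------------------------
        stage = "meta"
        meta_results: dict[str, pd.DataFrame] = {}
        meta_sets: dict[str, sumstats_io.SummaryStatSet] = {}
        if config.stages.get("meta", True):
            for cyt in cytokines:
                cohort_sets = {cohort: panel.sumstats[(cyt, cohort)]
                               for cohort in config.cohort_order
                               if (cyt, cohort) in panel.sumstats}
                mdf = meta_mod.meta_analyze(cohort_sets, config.cohort_order,
                                            trait_id=cyt)
                meta_results[cyt] = mdf
                meta_sets[cyt] = meta_mod.meta_to_sumstats(mdf, cyt)
                counts[f"meta_{cyt}"] = _write(mdf, out / "meta" / f"{cyt}.tsv")
            lambdas = pd.DataFrame(
                [{"trait_id": c, "lambda": meta_mod.genomic_lambda(meta_results[c]["P_META"])}
                 for c in cytokines])
            _write(lambdas, out / "meta" / "lambda.tsv")

        # ---- loci + replication ------------------------------------------
        stage = "loci"
        all_loci: dict[str, list[loci_mod.Locus]] = {}
        if config.stages.get("loci", True) and meta_results:
            for cyt in cytokines:
                all_loci[cyt] = loci_mod.call_loci(
                    meta_results[cyt], panel.ld, gene_windows.get(cyt),
                    p_threshold=config.gw_p, r2_threshold=config.clump_r2_loci,
                    flank_bp=config.flank_bp, trait_id=cyt)
            loci_df = pd.concat([loci_mod.loci_table(all_loci[c]) for c in cytokines],
                                ignore_index=True)
            counts["loci"] = _write(loci_df, out / "loci" / "loci.tsv")

            reports = []
            for cyt in cytokines:
                for ref_cohort in config.cohort_order:
                    if (cyt, ref_cohort) not in panel.sumstats:
                        continue
                    ref = panel.sumstats[(cyt, ref_cohort)]
                    sig = ref.records.loc[ref.records["P"] < config.gw_p, "SNP"].tolist()
                    targets = {c: panel.sumstats[(cyt, c)] for c in config.cohort_order
                               if c != ref_cohort and (cyt, c) in panel.sumstats}
                    reports.extend(loci_mod.replication_rates(ref, targets, sig))
            rep_df = pd.DataFrame([{
                "reference": r.reference_cohort, "target": r.target_cohort,
                "trait_id": r.trait_id, "n_significant": r.n_significant,
                "n_replicated": r.n_replicated, "rate": r.rate} for r in reports])
            counts["replication"] = _write(rep_df, out / "loci" / "replication.tsv")
            _write(loci_mod.replication_summary(reports),
                   out / "loci" / "replication_summary.tsv")

        # ---- finemap ------------------------------------------------------
        stage = "finemap"
        if config.stages.get("finemap", True) and all_loci:
            cs_frames = []
            for cyt, lcs in all_loci.items():
                mdf = meta_results[cyt]
                for lc in lcs:
                    lead_pos = int(mdf.set_index("SNP").at[lc.lead_variant_id, "BP"])
                    region = mdf[(mdf["CHR"].astype(str) == str(lc.chrom))
                                 & (mdf["BP"] >= lead_pos - config.flank_bp)
                                 & (mdf["BP"] <= lead_pos + config.flank_bp)]
                    cs = finemap.credible_set(
                        region.rename(columns={"BETA_HAT": "BETA", "SE_HAT": "SE"}),
                        coverage=config.coverage, locus_id=lc.locus_id,
                        lead_variant_id=lc.lead_variant_id)
                    tbl = finemap.credible_set_table(cs)
                    tbl.insert(0, "trait_id", cyt)
                    cs_frames.append(tbl)
            if cs_frames:
                cs_df = pd.concat(cs_frames, ignore_index=True)
                counts["finemap"] = _write(cs_df, out / "finemap" / "credible_sets.tsv")
            # explained variance per trait from independent leads
            ev_rows = []
            for cyt, lcs in all_loci.items():
                idx = meta_results[cyt].set_index("SNP")
                leads = [(idx.at[lc.lead_variant_id, "EAF"],
                          idx.at[lc.lead_variant_id, "BETA_HAT"]) for lc in lcs]
                ev_rows.append({"trait_id": cyt, "n_loci": len(lcs),
                                "r2_total": meta_mod.explained_variance(leads)})
            _write(pd.DataFrame(ev_rows), out / "finemap" / "explained_variance.tsv")

        # ---- ldsc ---------------------------------------------------------
        stage = "ldsc"
        if config.stages.get("ldsc", True) and meta_results:
            ell = ldsc_mod.ld_scores(panel.ld)
            order = panel.ld.variant_ids
            long_rows, mat = [], {}
            zs, ns = {}, {}
            for cyt in cytokines:
                idx = meta_results[cyt].set_index("SNP").reindex(order)
                zs[cyt] = idx["Z_META"].to_numpy(float)
                ns[cyt] = idx["N_TOTAL"].to_numpy(float)
            for i, c1 in enumerate(cytokines):
                for c2 in cytokines[i + 1:]:
                    res = ldsc_mod.rg_regression(zs[c1], zs[c2], np.nanmean(ns[c1]),
                                                 np.nanmean(ns[c2]), ell,
                                                 trait1=c1, trait2=c2)
                    long_rows.append({
                        "trait1": c1, "trait2": c2, "h2_1": res.h2_1,
                        "h2_1_se": res.h2_1_se, "h2_2": res.h2_2,
                        "h2_2_se": res.h2_2_se, "gencov": res.gencov,
                        "gencov_se": res.gencov_se, "rg": res.rg,
                        "rg_se": res.rg_se, "intercept_1": res.intercept_1,
                        "intercept_2": res.intercept_2,
                        "cross_intercept": res.cross_intercept,
                        "status": res.status})
                    mat[(c1, c2)] = res.rg if res.rg is not None else np.nan
            counts["ldsc"] = _write(pd.DataFrame(long_rows), out / "ldsc" / "ldsc_long.tsv")
            rg_mat = pd.DataFrame(np.eye(len(cytokines)), index=cytokines,
                                  columns=cytokines)
            for (c1, c2), v in mat.items():
                rg_mat.loc[c1, c2] = rg_mat.loc[c2, c1] = v
            rg_mat.index.name = "trait"
            rg_mat.reset_index().to_csv(out / "ldsc" / "rg_matrix.tsv", sep="\t",
                                        index=False, na_rep=".", float_format="%.10g")

        # ---- mr network ---------------------------------------------------
        stage = "mr_network"
        network_df = pd.DataFrame()
        if config.stages.get("mr_network", True) and meta_results:
            network_df = mr_mod.mr_network(
                meta_results, meta_sets, gene_windows, panel.ld,
                flank_bp=config.flank_bp, p_cut=config.instrument_p,
                r2_cut=config.clump_r2_instruments,
                het_exclude=config.het_exclude, wm_seed=config.seed)
            counts["mr_network"] = _write(network_df, out / "mr" / "network.tsv")

        # ---- disease screen ----------------------------------------------
        stage = "disease_screen"
        screen_df = pd.DataFrame()
        if config.stages.get("disease_screen", True) and meta_results:
            screen_df = mr_mod.disease_screen(
                meta_results, disease_sets, gene_windows, panel.ld,
                flank_bp=config.flank_bp, p_cut=config.instrument_p,
                r2_cut=config.clump_r2_instruments,
                het_exclude=config.het_exclude, wm_seed=config.seed)
            counts["disease_screen"] = _write(screen_df, out / "mr" / "screen.tsv")

        # ---- coloc --------------------------------------------------------
        stage = "coloc"
        coloc_rows = []
        if config.stages.get("coloc", True) and len(screen_df):
            hits = screen_df[(screen_df["method"].isin(["ivw_fe", "wald"]))
                             & (screen_df["q"] < config.fdr_level)]
            for _, hit in hits.iterrows():
                cyt, dis = hit["exposure"], hit["outcome"]
                chrom, start, end = gene_windows[cyt]
                mdf = meta_results[cyt]
                reg1 = mdf[(mdf["CHR"].astype(str) == str(chrom))
                           & (mdf["BP"] >= start - config.flank_bp)
                           & (mdf["BP"] <= end + config.flank_bp)]
                reg2 = disease_sets[dis].records
                res = coloc_mod.coloc_abf(
                    reg1.rename(columns={"BETA_HAT": "BETA", "SE_HAT": "SE"}),
                    reg2, prior_sd2=finemap.PRIOR_SD_BINARY,
                    region_id=f"{cyt}~{dis}")
                _, row = coloc_mod.coloc_call(res, config.coloc_threshold)
                coloc_rows.append(row)
            counts["coloc"] = _write(pd.DataFrame(coloc_rows),
                                     out / "coloc" / "coloc.tsv")

        # ---- twas ---------------------------------------------------------
        stage = "twas"
        if config.stages.get("twas", True) and meta_results:
            twas_df = mr_mod.twas_mr(eqtl_sets, meta_sets, gene_windows_by_gene,
                                     panel.ld, flank_bp=config.flank_bp,
                                     p_cut=config.instrument_p,
                                     r2_cut=config.clump_r2_eqtl,
                                     wm_seed=config.seed)
            counts["twas"] = _write(twas_df, out / "mr" / "twas.tsv")
            twas_dis = mr_mod.twas_mr(eqtl_sets, disease_sets, gene_windows_by_gene,
                                      panel.ld, flank_bp=config.flank_bp,
                                      p_cut=config.instrument_p,
                                      r2_cut=config.clump_r2_eqtl,
                                      wm_seed=config.seed)
            _write(twas_dis, out / "mr" / "twas_disease.tsv")
            chains = _chain_table(twas_df, twas_dis, config.fdr_level)
            _write(chains, out / "mr" / "chains.tsv")

        # ---- report -------------------------------------------------------
        stage = "report"
        report = {}
        if config.stages.get("report", True) and meta_results:
            report = summarize(meta_results, all_loci, network_df, screen_df,
                               pd.DataFrame(coloc_rows),
                               rep_summary=pd.read_csv(
                                   out / "loci" / "replication_summary.tsv", sep="\t")
                               if (out / "loci" / "replication_summary.tsv").exists()
                               else pd.DataFrame(),
                               fdr_level=config.fdr_level,
                               hla_exclusion=config.hla_exclusion)
            (out / "report").mkdir(exist_ok=True)
            (out / "report" / "summary.json").write_text(
                json.dumps(report, indent=2, sort_keys=True, default=float))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "package": "cytogen", "version": __version__, "seed": config.seed,
        "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "stage_row_counts": {k: int(v) for k, v in sorted(counts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return report


def _chain_table(twas_cyt: pd.DataFrame, twas_dis: pd.DataFrame,
                 fdr_level: float) -> pd.DataFrame:
    """Gene -> cytokine -> disease chains: join the two TWAS runs on gene id."""
    def sig(df):
        if df.empty:
            return df
        m = df["method"].isin(["ivw_fe", "wald"]) & (df["q"] < fdr_level)
        return df.loc[m, ["exposure", "outcome", "beta", "q"]]
    a, b = sig(twas_cyt), sig(twas_dis)
    if a.empty or b.empty:
        return pd.DataFrame(columns=["gene", "cytokine", "disease",
                                     "beta_gene_cytokine", "beta_gene_disease"])
    merged = a.merge(b, on="exposure", suffixes=("_cyt", "_dis"))
    return pd.DataFrame({
        "gene": merged["exposure"], "cytokine": merged["outcome_cyt"],
        "disease": merged["outcome_dis"],
        "beta_gene_cytokine": merged["beta_cyt"],
        "beta_gene_disease": merged["beta_dis"]})


def summarize(meta_results: dict[str, pd.DataFrame],
              all_loci: dict[str, list], network_df: pd.DataFrame,
              screen_df: pd.DataFrame, coloc_df: pd.DataFrame,
              rep_summary: pd.DataFrame, fdr_level: float = 0.05,
              hla_exclusion: tuple[str, int, int] | None = None) -> dict:
    """Summary statistics over the stage outputs.

    Includes the Spearman rank correlation between lead-variant MAF and
    |beta|, a Mann-Whitney comparison of cis vs trans lead |beta|, a
    pleiotropy histogram of merged loci by number of associated cytokines
    (optionally excluding an HLA-like interval), network/screen/coloc counts
    and cross-assay replication medians.
    """
    report: dict = {}
    locus_counts = {}
    lead_rows = []
    for cyt, lcs in all_loci.items():
        labels = [lc.label for lc in lcs]
        locus_counts[cyt] = {"total": len(lcs),
                             "cis": labels.count("cis"),
                             "trans": labels.count("trans")}
        idx = meta_results[cyt].set_index("SNP")
        for lc in lcs:
            lead_rows.append({
                "trait": cyt, "chrom": lc.chrom,
                "pos": int(idx.at[lc.lead_variant_id, "BP"]),
                "label": lc.label,
                "maf": min(idx.at[lc.lead_variant_id, "EAF"],
                           1 - idx.at[lc.lead_variant_id, "EAF"]),
                "abs_beta": abs(idx.at[lc.lead_variant_id, "BETA_HAT"])})
    report["locus_counts"] = locus_counts
    leads = pd.DataFrame(lead_rows)

    if len(leads) >= 3:
        rho, rho_p = stats.spearmanr(leads["maf"], leads["abs_beta"])
        report["maf_beta_spearman"] = {"rho": float(rho), "p": float(rho_p),
                                       "n": int(len(leads))}
    else:
        report["maf_beta_spearman"] = {"status": "fewer than 3 leads"}

    cis_b = leads.loc[leads["label"] == "cis", "abs_beta"]
    trans_b = leads.loc[leads["label"] == "trans", "abs_beta"]
    if len(cis_b) >= 1 and len(trans_b) >= 1:
        u, p = stats.mannwhitneyu(cis_b, trans_b, alternative="two-sided")
        report["cis_trans_abs_beta"] = {
            "U": float(u), "p": float(p), "n_cis": int(len(cis_b)),
            "n_trans": int(len(trans_b)),
            "median_cis": float(cis_b.median()),
            "median_trans": float(trans_b.median())}
    else:
        report["cis_trans_abs_beta"] = {"status": "need cis and trans leads"}

    # pleiotropy: merge lead positions across traits into shared loci
    if len(leads):
        lf = leads
        if hla_exclusion is not None:
            chrom, start, end = hla_exclusion
            lf = lf[~((lf["chrom"].astype(str) == str(chrom))
                      & (lf["pos"] >= start) & (lf["pos"] <= end))]
        lf = lf.sort_values(["chrom", "pos"], kind="mergesort")
        new = (lf["chrom"] != lf["chrom"].shift()) | \
              (lf["pos"] - lf["pos"].shift() > loci_mod.LOCUS_SEPARATION_BP)
        lf = lf.assign(group=new.cumsum())
        per_locus = lf.groupby("group")["trait"].nunique()
        hist = per_locus.value_counts().sort_index()
        report["pleiotropy_histogram"] = {int(k): int(v) for k, v in hist.items()}
        report["n_pleiotropic_loci"] = int((per_locus > 1).sum())

    def _edge_counts(df):
        if df.empty:
            return {"tested": 0, "significant": 0, "positive": 0, "negative": 0}
        prim = df[df["method"].isin(["ivw_fe", "wald"])]
        sig = prim[prim["q"] < fdr_level]
        return {"tested": int(len(prim)), "significant": int(len(sig)),
                "positive": int((sig["beta"] > 0).sum()),
                "negative": int((sig["beta"] < 0).sum())}

    report["network_edges"] = _edge_counts(network_df)
    report["screen_hits"] = _edge_counts(screen_df)
    report["coloc"] = {
        "tested": int(len(coloc_df)),
        "colocalized": int(coloc_df["colocalized"].sum()) if len(coloc_df) else 0}
    if len(rep_summary):
        report["replication_medians"] = [
            {"reference": r["reference"], "target": r["target"],
             "median_rate": float(r["median"]), "q1": float(r["q1"]),
             "q3": float(r["q3"]), "n_traits": int(r["n_traits"])}
            for _, r in rep_summary.iterrows()]
    return report
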