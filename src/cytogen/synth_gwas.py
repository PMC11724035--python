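"""Seeded synthetic GWAS summary statistics with LD structure.

Everything downstream (meta-analysis, clumping, fine-mapping, LDSC, MR,
colocalization) consumes marginal summary statistics, so traits are simulated
directly at that level under the regression-with-summary-statistics (RSS)
model: given a signed LD matrix R and joint standardized effects b, the
marginal z-vector of one cohort is

    z ~ MVN( sqrt(n) * R b,  R )

on the standardized-genotype scale. Standardized betas and SEs are then
recovered from z and the effect-allele frequency f via
beta = z / sqrt(2 f (1-f) (n + z^2)), se = 1 / sqrt(2 f (1-f) (n + z^2)).

Genes live on disjoint LD blocks (AR(1) correlation within a block, zero
between blocks), which makes one Cholesky per block exact and keeps the
cross-chromosome independence assumption of LD-score regression literal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cytogen")

RIDGE = 1e-8
PSD_TOL = -1e-8


# ---------------------------------------------------------------------------
# LD containers
# ---------------------------------------------------------------------------

@dataclass
class LDMatrix:
    """One LD block: signed pairwise correlation over position-sorted variants."""

    variant_ids: list[str]
    positions: np.ndarray  # 1-based bp
    chrom: str
    R: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.variant_ids)
        if self.R.shape != (m, m):
            raise ValueError("R shape does not match variant count")
        if len(set(self.variant_ids)) != m:
            raise ValueError("variant ids must be unique")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted ascending")
        if not np.allclose(self.R, self.R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-12):
            raise ValueError("R must have unit diagonal")
        if np.max(np.abs(self.R)) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if m > 1:
            w = np.linalg.eigvalsh(self.R)
            if w[0] < PSD_TOL:
                raise ValueError(f"R is not PSD (min eigenvalue {w[0]:.3g})")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor, with a ridge of 1e-8 on the diagonal if needed."""
        try:
            return np.linalg.cholesky(self.R)
        except np.linalg.LinAlgError:
            return np.linalg.cholesky(self.R + RIDGE * np.eye(self.n_variants))

    def r2(self) -> np.ndarray:
        return self.R ** 2


class LDReference:
    """A set of disjoint LD blocks with variant-id lookup; cross-block r = 0."""

    def __init__(self, blocks: list[LDMatrix]):
        self.blocks = list(blocks)
        self._index: dict[str, tuple[int, int]] = {}
        for bi, blk in enumerate(self.blocks):
            for vi, vid in enumerate(blk.variant_ids):
                if vid in self._index:
                    raise ValueError(f"variant {vid} appears in two LD blocks")
                self._index[vid] = (bi, vi)

    @property
    def variant_ids(self) -> list[str]:
        return [v for blk in self.blocks for v in blk.variant_ids]

    def __contains__(self, vid: str) -> bool:
        return vid in self._index

    def block_of(self, vid: str) -> tuple[int, int]:
        return self._index[vid]

    def r2_pair(self, vid1: str, vid2: str) -> float:
        b1, i1 = self._index[vid1]
        b2, i2 = self._index[vid2]
        if b1 != b2:
            return 0.0
        return float(self.blocks[b1].R[i1, i2] ** 2)

    def variant_table(self) -> pd.DataFrame:
        rows = [(v, blk.chrom, int(p))
                for blk in self.blocks
                for v, p in zip(blk.variant_ids, blk.positions)]
        return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"])


def ar1_ld_matrix(n_variants: int, ar1_rho: float, chrom: str = "1",
                  start_pos: int = 1, spacing: int = 2000,
                  id_prefix: str = "rs") -> LDMatrix:
    """AR(1) LD block: ``R[j, k] = rho^|j-k|``, positions on a regular grid.

    AR(1) correlation matrices are PSD for 0 <= rho < 1; rho >= 1 is rejected.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not (0.0 <= ar1_rho < 1.0):
        raise ValueError(f"ar1_rho must be in [0, 1), got {ar1_rho}")
    idx = np.arange(n_variants)
    R = ar1_rho ** np.abs(idx[:, None] - idx[None, :])
    positions = start_pos + idx * spacing
    ids = [f"{id_prefix}{chrom}_{p}" for p in positions]
    return LDMatrix(variant_ids=ids, positions=positions, chrom=str(chrom), R=R)


# ---------------------------------------------------------------------------
# Ground truth and configuration
# ---------------------------------------------------------------------------

@dataclass
class TrueArchitecture:
    """Planted joint effects for one trait, the ground truth for recovery tests.

    ``causal_effects`` maps variant_id -> joint standardized effect b (SD of
    trait per allele on the standardized-genotype scale). ``assay_shift``
    rescales effects per cohort (assay heterogeneity); ``cohort_specific``
    maps variant_id -> the set of cohorts in which its effect exists at all.
    """

    causal_effects: dict[str, float]
    cis_gene: str | None = None
    trait_h2: float = 0.0
    assay_shift: dict[str, float] = field(default_factory=dict)
    cohort_specific: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(b * b for b in self.causal_effects.values())
        if self.trait_h2 and total > self.trait_h2 + 1e-9:
            raise ValueError(
                f"sum of squared effects {total:.4g} exceeds trait_h2 {self.trait_h2}")
        for c, s in self.assay_shift.items():
            if s <= 0:
                raise ValueError(f"assay_shift for {c} must be > 0")

    def effects_for_cohort(self, cohort_id: str) -> dict[str, float]:
        shift = self.assay_shift.get(cohort_id, 1.0)
        out = {}
        for vid, b in self.causal_effects.items():
            allowed = self.cohort_specific.get(vid)
            if allowed is not None and cohort_id not in allowed:
                continue
            out[vid] = b * shift
        return out


@dataclass
class SimConfig:
    """Stated world for the synthetic three-cohort cytokine panel.

    Defaults emulate a typical multi-assay design: three non-overlapping European
    cohorts with very different sample sizes (immunoassay ~11k, Olink ~21k,
    SomaScan ~35k), 40-cytokine panels that only partially overlap, one
    200-variant AR(1) LD block per encoding gene, and binary disease
    outcomes driven by configurable causal cytokine effects.
    """

    n_variants: int = 200                 # per LD block / gene region
    ar1_rho: float = 0.9                  # strongest block; ~2 kb spacing
    ar1_rho_min: float = 0.3              # weakest block; LD varies across genes
    spacing: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    sample_sizes: dict[str, int] = field(
        default_factory=lambda: {"YFS_FINRISK": 11000, "SCALLOP": 21000, "DECODE": 35000})
    panel_overlap: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 1
    cis_effect: float = 0.15              # joint standardized beta of the planted cis variant
    n_cis: int = 1
    trans_effects: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    assay_shift: dict[str, dict[str, float]] = field(default_factory=dict)  # cytokine -> cohort -> shift
    cohort_specific: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    palindromic_frac: float = 0.05
    disease_params: dict = field(default_factory=lambda: {
        "prevalence": 0.1, "theta_true": 0.3, "n_case": 20000, "n_control": 180000})

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    @property
    def cohorts(self) -> list[str]:
        return list(self.sample_sizes)


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def _alleles(n: int, palindromic_frac: float, rng: np.random.Generator):
    """Synthetic biallelic pairs: A/G, with a fraction of palindromic A/T."""
    pal = rng.random(n) < palindromic_frac
    ea = np.where(pal, "A", "A")
    oa = np.where(pal, "T", "G")
    return ea.astype(object), oa.astype(object)


def _resolve_alleles(blk: LDMatrix, alleles, palindromic_frac: float,
                     rng: np.random.Generator):
    """Alleles for one block: from the shared panel map if given, else drawn.

    Alleles are a property of the variant, not the trait — simulators run on
    a common panel must share one map or cross-trait harmonization sees
    spurious mismatches.
    """
    if alleles is None:
        return _alleles(blk.n_variants, palindromic_frac, rng)
    ea = np.array([alleles[v][0] for v in blk.variant_ids], dtype=object)
    oa = np.array([alleles[v][1] for v in blk.variant_ids], dtype=object)
    return ea, oa


def draw_alleles(variant_ids, palindromic_frac: float,
                 rng: np.random.Generator) -> dict[str, tuple[str, str]]:
    """One panel-wide allele map: variant_id -> (effect, other)."""
    ea, oa = _alleles(len(variant_ids), palindromic_frac, rng)
    return {v: (e, o) for v, e, o in zip(variant_ids, ea, oa)}


def draw_eaf(n: int, maf_range: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    lo, hi = maf_range
    return rng.uniform(lo, hi, size=n)


def _records_from_z(ld: LDMatrix, z: np.ndarray, eaf: np.ndarray, n: int,
                    ea, oa) -> pd.DataFrame:
    denom = np.sqrt(2.0 * eaf * (1.0 - eaf) * (n + z ** 2))
    beta = z / denom
    se = 1.0 / denom
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "SNP": ld.variant_ids, "CHR": ld.chrom, "BP": ld.positions,
        "EA": ea, "OA": oa, "EAF": eaf, "BETA": beta, "SE": se,
        "P": p, "N": float(n), "Z": z,
    })


def _simulate_block_z(ld: LDMatrix, b: np.ndarray, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """One draw of marginal z for a block: z ~ MVN(sqrt(n) R b, R)."""
    mean = np.sqrt(n) * (ld.R @ b)
    eps = rng.standard_normal(ld.n_variants)
    return mean + ld.cholesky() @ eps


def simulate_cohort_sumstats(ld: LDMatrix | LDReference, arch: TrueArchitecture,
                             n: int, eaf: np.ndarray | dict[str, float],
                             seed: int, trait_id: str = "trait",
                             cohort_id: str = "cohort",
                             palindromic_frac: float = 0.05,
                             alleles: dict[str, tuple[str, str]] | None = None):
    """Simulate one trait x cohort GWAS under the RSS model.

    ``eaf`` gives effect-allele frequencies in (0, 0.5] (minor-allele
    orientation), either as an array over all LD variants in order or a
    variant_id -> frequency map. The same seed always yields the same set.
    """
    from .sumstats_io import SummaryStatSet

    if n <= 1:
        raise ValueError("sample size must be > 1")
    blocks = ld.blocks if isinstance(ld, LDReference) else [ld]
    all_ids = [v for blk in blocks for v in blk.variant_ids]
    if isinstance(eaf, dict):
        f = np.array([eaf[v] for v in all_ids], dtype=float)
    else:
        f = np.asarray(eaf, dtype=float)
    if np.any(f <= 0) or np.any(f > 0.5):
        raise ValueError("eaf must lie in (0, 0.5]")
    unknown = set(arch.causal_effects) - set(all_ids)
    if unknown:
        raise ValueError(f"architecture variants missing from LD: {sorted(unknown)[:5]}")

    effects = arch.effects_for_cohort(cohort_id)
    rng = np.random.default_rng(seed)
    allele_rng = np.random.default_rng(seed)  # alleles drawn first, stable per seed
    frames = []
    offset = 0
    for blk in blocks:
        m = blk.n_variants
        b = np.array([effects.get(v, 0.0) for v in blk.variant_ids])
        z = _simulate_block_z(blk, b, n, rng)
        ea, oa = _resolve_alleles(blk, alleles, palindromic_frac, allele_rng)
        frames.append(_records_from_z(blk, z, f[offset:offset + m], n, ea, oa))
        offset += m
    records = pd.concat(frames, ignore_index=True)
    return SummaryStatSet(trait_id=trait_id, cohort_id=cohort_id, records=records,
                          trait_type="quantitative")


def simulate_disease_gwas(ld: LDMatrix | LDReference,
                          instrument_effects: dict[str, float],
                          theta_true: float, n_case: int, n_control: int,
                          seed: int, eaf: np.ndarray | dict[str, float],
                          trait_id: str = "disease",
                          cohort_id: str = "disease_gwas",
                          palindromic_frac: float = 0.05,
                          alleles: dict[str, tuple[str, str]] | None = None):
    """Binary-disease GWAS on the log-odds scale.

    ``instrument_effects`` are the *marginal* exposure effects beta_X per
    variant on the standardized-genotype scale (SD of exposure per genotype
    SD, i.e. (R b)_j of the exposure's architecture). Emitted log-odds betas
    are per allele, matching the per-allele scale that downstream MR
    reconstructs for the exposure: each variant gets
    beta_Y ~ N(theta_true * beta_X / sqrt(2 f (1-f)), se^2) with
    se = 1/sqrt(2 f (1-f) n_eff), n_eff = 4 / (1/n_case + 1/n_control), and
    noise correlated across LD exactly as in
    :func:`simulate_cohort_sumstats` — so the per-allele ratio
    beta_Y / beta_X,allele equals theta_true at every instrument.
    """
    from .sumstats_io import SummaryStatSet

    if not np.isfinite(theta_true):
        raise ValueError("theta_true must be finite")
    if n_case < 100 or n_control < 100:
        raise ValueError("need at least 100 cases and 100 controls")
    blocks = ld.blocks if isinstance(ld, LDReference) else [ld]
    all_ids = [v for blk in blocks for v in blk.variant_ids]
    if isinstance(eaf, dict):
        f = np.array([eaf[v] for v in all_ids], dtype=float)
    else:
        f = np.asarray(eaf, dtype=float)
    n_eff = 4.0 / (1.0 / n_case + 1.0 / n_control)

    rng = np.random.default_rng(seed)
    allele_rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for blk in blocks:
        m = blk.n_variants
        fb = f[offset:offset + m]
        bx = np.array([instrument_effects.get(v, 0.0) for v in blk.variant_ids])
        scale = np.sqrt(2.0 * fb * (1.0 - fb))
        se = 1.0 / (scale * np.sqrt(n_eff))
        eps = blk.cholesky() @ rng.standard_normal(m)
        beta = theta_true * bx / scale + se * eps
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        ea, oa = _resolve_alleles(blk, alleles, palindromic_frac, allele_rng)
        frames.append(pd.DataFrame({
            "SNP": blk.variant_ids, "CHR": blk.chrom, "BP": blk.positions,
            "EA": ea, "OA": oa, "EAF": fb, "BETA": beta, "SE": se,
            "P": p, "N": float(n_case + n_control), "Z": z,
        }))
        offset += m
    records = pd.concat(frames, ignore_index=True)
    return SummaryStatSet(trait_id=trait_id, cohort_id=cohort_id, records=records,
                          trait_type="binary")


@dataclass
class SimulatedPanel:
    """Everything one simulate_panel call produced, truth registry included."""

    sumstats: dict[tuple[str, str], object]       # (cytokine, cohort) -> SummaryStatSet
    truths: dict[str, TrueArchitecture]           # cytokine -> planted architecture
    ld: LDReference
    gene_panel: pd.DataFrame                      # BED-like, 0-based half-open
    eaf: dict[str, float]
    config: SimConfig
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)


def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Simulate the full multi-cohort cytokine panel.

    One AR(1) LD block per cytokine's encoding gene; each cytokine gets
    ``n_cis`` planted cis variants in its own block plus any configured trans
    effects in other genes' blocks. Cytokines absent from a cohort's panel
    produce no SummaryStatSet for that cohort; ``assay_shift`` != 1 and
    ``cohort_specific`` entries plant real heterogeneity.
    """
    if not config.panel_overlap:
        raise ValueError("panel_overlap must name at least one cytokine")
    for cyt, cohorts in config.panel_overlap.items():
        if not cohorts:
            raise ValueError(f"cytokine {cyt} measured in zero cohorts")
        unknown = set(cohorts) - set(config.cohorts)
        if unknown:
            raise ValueError(f"unknown cohorts for {cyt}: {sorted(unknown)}")

    ss = np.random.SeedSequence(config.seed)
    cytokines = list(config.panel_overlap)
    # layout: one block per cytokine gene, round-robin over 22 autosomes,
    # 10 Mb apart within a chromosome so loci never chain across genes
    blocks, gene_rows = [], []
    span = config.n_variants * config.spacing
    # LD strength varies across gene regions (real genomes are heterogeneous;
    # constant LD would also leave the LD-score regression design degenerate)
    lo = min(config.ar1_rho_min, config.ar1_rho)
    rhos = (np.linspace(lo, config.ar1_rho, len(cytokines))
            if len(cytokines) > 1 else np.array([config.ar1_rho]))
    for gi, cyt in enumerate(cytokines):
        chrom = str(gi % 22 + 1)
        start = 1_000_000 + (gi // 22) * 10_000_000
        blk = ar1_ld_matrix(config.n_variants, float(rhos[gi]), chrom=chrom,
                            start_pos=start, spacing=config.spacing,
                            id_prefix=f"rs{cyt}_")
        blocks.append(blk)
        # gene body sits in the middle third of the block (BED, 0-based half-open)
        gene_rows.append({"chrom": chrom, "start": start - 1 + span // 3,
                          "end": start - 1 + 2 * span // 3,
                          "gene_id": f"{cyt}_gene", "cytokine_id": cyt})
    ld = LDReference(blocks)
    gene_panel = pd.DataFrame(gene_rows)

    eaf_rng = np.random.default_rng(ss.spawn(1)[0])
    eaf = {}
    for blk in blocks:
        f = draw_eaf(blk.n_variants, config.maf_range, eaf_rng)
        eaf.update(dict(zip(blk.variant_ids, f)))
    alleles = draw_alleles(ld.variant_ids, config.palindromic_frac, eaf_rng)

    truths: dict[str, TrueArchitecture] = {}
    for gi, cyt in enumerate(cytokines):
        blk = blocks[gi]
        effects: dict[str, float] = {}
        # cis causal variants, centred in the gene body
        centre = blk.n_variants // 2
        step = max(blk.n_variants // (4 * max(config.n_cis, 1)), 1)
        for k in range(config.n_cis):
            effects[blk.variant_ids[centre + k * step]] = config.cis_effect
        # trans effects sit at the donor cytokine's planted cis causal variant:
        # a mediated effect (donor raises this trait) makes the marginal betas
        # proportional across the donor's whole LD block, as MR assumes
        for gene_cyt, b in config.trans_effects.get(cyt, []):
            tblk = blocks[cytokines.index(gene_cyt)]
            vid = tblk.variant_ids[tblk.n_variants // 2]
            effects[vid] = effects.get(vid, 0.0) + b
        truths[cyt] = TrueArchitecture(
            causal_effects=effects, cis_gene=f"{cyt}_gene",
            trait_h2=sum(v * v for v in effects.values()) + 1e-9,
            assay_shift=config.assay_shift.get(cyt, {}),
            cohort_specific=config.cohort_specific.get(cyt, {}))

    sumstats: dict[tuple[str, str], object] = {}
    child_seeds = ss.spawn(len(cytokines) * len(config.cohorts) + 1)[1:]
    k = 0
    for cyt in cytokines:
        for cohort in config.cohorts:
            seed_k = child_seeds[k]
            k += 1
            if cohort not in config.panel_overlap[cyt]:
                continue
            sumstats[(cyt, cohort)] = simulate_cohort_sumstats(
                ld, truths[cyt], config.sample_sizes[cohort], eaf,
                seed=seed_k, trait_id=cyt, cohort_id=cohort,
                alleles=alleles)
    return SimulatedPanel(sumstats=sumstats, truths=truths, ld=ld,
                          gene_panel=gene_panel, eaf=eaf, config=config,
                          alleles=alleles)


def marginal_effects(ld: LDReference | LDMatrix, arch: TrueArchitecture,
                     cohort_id: str = "") -> dict[str, float]:
    """Marginal standardized effects (R b)_j implied by a joint architecture."""
    blocks = ld.blocks if isinstance(ld, LDReference) else [ld]
    effects = arch.effects_for_cohort(cohort_id) if cohort_id else dict(arch.causal_effects)
    out: dict[str, float] = {}
    for blk in blocks:
        b = np.array([effects.get(v, 0.0) for v in blk.variant_ids])
        if not b.any():
            continue
        marg = blk.R @ b
        for v, m in zip(blk.variant_ids, marg):
            if m != 0.0:
                out[v] = float(m)
    return out


def simulate_eqtl_exposures(panel: SimulatedPanel, seed: int, n: int = 30000,
                            cis_effect: float = 0.2):
    """Whole-blood cis-eQTL exposure sets, one quantitative trait per gene.

    Each gene's expression gets a single planted cis causal variant (offset
    from the cytokine's, so expression->cytokine relationships run through
    LD, not identity) simulated on the same LD reference.
    """
    out = {}
    cytokines = list(panel.truths)
    ss = np.random.SeedSequence(seed)
    for child, cyt in zip(ss.spawn(len(cytokines)), cytokines):
        gi = cytokines.index(cyt)
        blk = panel.ld.blocks[gi]
        vid = blk.variant_ids[blk.n_variants // 2 + 2]
        arch = TrueArchitecture(causal_effects={vid: cis_effect},
                                cis_gene=f"{cyt}_gene",
                                trait_h2=cis_effect ** 2 + 1e-9)
        out[f"{cyt}_gene"] = simulate_cohort_sumstats(
            panel.ld, arch, n, panel.eaf, seed=child,
            trait_id=f"{cyt}_gene", cohort_id="eQTLGen_syn",
            alleles=panel.alleles)
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_ld_reference(ld: LDReference, out_dir) -> None:
    """Dense per-block matrix TSVs plus a sidecar variant index TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for bi, blk in enumerate(ld.blocks):
        fn = f"ld_block_{bi:03d}.tsv"
        pd.DataFrame(blk.R, index=blk.variant_ids,
                     columns=blk.variant_ids).to_csv(out_dir / fn, sep="\t",
                                                     float_format="%.10g")
        for v, p in zip(blk.variant_ids, blk.positions):
            index_rows.append({"variant_id": v, "chrom": blk.chrom,
                               "pos": int(p), "block_file": fn})
    pd.DataFrame(index_rows).to_csv(out_dir / "variants.tsv", sep="\t", index=False)


def read_ld_reference(ld_dir) -> LDReference:
    ld_dir = Path(ld_dir)
    idx = pd.read_csv(ld_dir / "variants.tsv", sep="\t", dtype={"chrom": str})
    blocks = []
    for fn, grp in idx.groupby("block_file", sort=True):
        mat = pd.read_csv(ld_dir / fn, sep="\t", index_col=0)
        blocks.append(LDMatrix(variant_ids=list(grp["variant_id"]),
                               positions=grp["pos"].to_numpy(),
                               chrom=str(grp["chrom"].iloc[0]),
                               R=mat.to_numpy()))
    return LDReference(blocks)


def write_gene_panel(gene_panel: pd.DataFrame, path) -> None:
    gene_panel.to_csv(path, sep="\t", index=False)


def write_truth_registry(truths: dict[str, TrueArchitecture], path) -> None:
    rows = []
    for cyt, arch in truths.items():
        for vid, b in arch.causal_effects.items():
            rows.append({"cytokine_id": cyt, "variant_id": vid, "b_joint": b,
                         "cis_gene": arch.cis_gene,
                         "cohorts": ";".join(sorted(arch.cohort_specific.get(vid, []))) or "all"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
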