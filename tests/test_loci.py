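"""Clumping, locus merging, cis/trans classification, replication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytogen import loci
from cytogen import synth_gwas as sg
from cytogen.loci import Locus

from conftest import make_sumstats
from oracles import brute_force_clump


def _ld_from_r2(snps, r2):
    """Tiny LDReference stand-in exposing r2_pair from a dict."""
    class _Fake:
        def __contains__(self, v):
            return v in snps

        def r2_pair(self, a, b):
            if a == b:
                return 1.0
            return r2.get((a, b), r2.get((b, a), 0.0))
    return _Fake()


class TestClump:
    def test_three_variant_example(self):
        rec = pd.DataFrame({"SNP": ["v1", "v2", "v3"], "CHR": "1",
                            "BP": [100, 200, 300],
                            "P": [1e-10, 1e-9, 1e-8]})
        ld = _ld_from_r2({"v1", "v2", "v3"}, {("v1", "v2"): 0.5})
        leads = loci.clump(rec, ld, p_threshold=0.1, r2_threshold=0.1,
                           window_bp=10000)
        assert set(leads) == {"v1", "v3"}

    def test_independent_variants_all_lead(self):
        rec = pd.DataFrame({"SNP": [f"v{i}" for i in range(5)], "CHR": "1",
                            "BP": np.arange(5) * 100, "P": [1e-9] * 5})
        ld = _ld_from_r2({f"v{i}" for i in range(5)}, {})
        assert len(loci.clump(rec, ld, 5e-8, 0.001, 10000)) == 5

    def test_single_significant_variant(self):
        rec = pd.DataFrame({"SNP": ["v1", "v2"], "CHR": "1", "BP": [1, 2],
                            "P": [1e-9, 0.5]})
        ld = _ld_from_r2({"v1", "v2"}, {})
        assert loci.clump(rec, ld, 5e-8, 0.001, 100) == ["v1"]

    def test_unknown_variant_excluded(self, caplog):
        rec = pd.DataFrame({"SNP": ["v1", "vX"], "CHR": "1", "BP": [1, 2],
                            "P": [1e-9, 1e-9]})
        ld = _ld_from_r2({"v1"}, {})
        with caplog.at_level("INFO", logger="cytogen"):
            leads = loci.clump(rec, ld, 5e-8, 0.001, 100)
        assert leads == ["v1"]
        assert "absent from the LD reference" in caplog.text

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_greedy(self, seed):
        """Randomized instances with <=12 variants agree with an exhaustive
        greedy oracle."""
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 13)
        snps = [f"v{i}" for i in range(m)]
        chroms = rng.choice(["1", "2"], m)
        pos = rng.integers(1, 500, m) * 100
        pvals = 10.0 ** rng.uniform(-12, 0, m)
        r2 = {}
        for i in range(m):
            for j in range(i + 1, m):
                if rng.random() < 0.4:
                    r2[(snps[i], snps[j])] = rng.random()
        rec = pd.DataFrame({"SNP": snps, "CHR": chroms, "BP": pos, "P": pvals})
        # unique (chrom,pos) to keep the tie-break well-defined
        rec = rec.drop_duplicates(["CHR", "BP"])
        ld = _ld_from_r2(set(rec["SNP"]), r2)
        got = loci.clump(rec, ld, 1e-4, 0.3, 5000)
        want = brute_force_clump(rec["SNP"], rec["CHR"], rec["BP"], rec["P"],
                                 ld.r2_pair, 1e-4, 0.3, 5000)
        assert got == want


class TestMergeToLoci:
    @staticmethod
    def _leads(positions, pvals, chrom="1"):
        return pd.DataFrame({"SNP": [f"v{i}" for i in range(len(positions))],
                             "CHR": chrom, "BP": positions, "P": pvals})

    def test_within_1mb_merges(self):
        lcs = loci.merge_to_loci(self._leads([1_000_000, 1_800_000], [1e-9, 1e-8]))
        assert len(lcs) == 1
        assert lcs[0].lead_variant_id == "v0"

    def test_beyond_1mb_separate(self):
        lcs = loci.merge_to_loci(self._leads([1_000_000, 2_500_000], [1e-9, 1e-8]))
        assert len(lcs) == 2

    def test_chained_merge_is_transitive(self):
        """1.0, 1.9, 2.8 Mb: consecutive gaps are 0.9 Mb, so all three chain
        into one locus even though the ends are 1.8 Mb apart."""
        lcs = loci.merge_to_loci(
            self._leads([1_000_000, 1_900_000, 2_800_000], [1e-8, 1e-10, 1e-9]))
        assert len(lcs) == 1
        assert lcs[0].lead_variant_id == "v1"
        assert lcs[0].span == (1_000_000, 2_800_000)

    def test_monotone_in_separation(self):
        rng = np.random.default_rng(3)
        leads = self._leads(sorted(rng.integers(1, 10_000_000, 30)),
                            10.0 ** rng.uniform(-12, -8, 30))
        counts = [len(loci.merge_to_loci(leads, sep))
                  for sep in (10_000, 100_000, 1_000_000, 10_000_000)]
        assert counts == sorted(counts, reverse=True)


class TestCisTrans:
    def _locus(self, chrom, lead="v1"):
        return Locus("l1", chrom, lead, 1e-9, [lead], (0, 0), trait_id="T")

    def test_upstream_within_flank_is_cis(self):
        lab = loci.classify_cis_trans(self._locus("1"), ("1", 1_000_000, 1_010_000),
                                      lead_pos=750_000)
        assert lab == "cis"

    def test_other_chromosome_is_trans(self):
        lab = loci.classify_cis_trans(self._locus("2"), ("1", 1_000_000, 1_010_000),
                                      lead_pos=1_000_000)
        assert lab == "trans"

    def test_boundary_is_closed(self):
        lab = loci.classify_cis_trans(self._locus("1"), ("1", 1_000_000, 1_010_000),
                                      lead_pos=700_000)  # exactly start - 300kb
        assert lab == "cis"

    def test_missing_window_gives_none(self):
        assert loci.classify_cis_trans(self._locus("1"), None, 100) is None


class TestReplication:
    def test_rate_arithmetic(self):
        ref = make_sumstats("T", "ref", [f"v{i}" for i in range(10)],
                            [0.1] * 10, [0.02] * 10)
        # 6 replicate (same sign, small p), 4 flip sign
        betas = [0.1] * 6 + [-0.1] * 4
        tgt = make_sumstats("T", "tgt", [f"v{i}" for i in range(10)],
                            betas, [0.02] * 10)
        rep = loci.replication_rates(ref, {"tgt": tgt},
                                     [f"v{i}" for i in range(10)])[0]
        assert rep.n_significant == 10
        assert rep.n_replicated == 6
        assert rep.rate == pytest.approx(0.6)

    def test_self_replication_is_one(self):
        ref = make_sumstats("T", "ref", ["v1", "v2"], [0.2, -0.2], [0.02, 0.02])
        rep = loci.replication_rates(ref, {"self": ref}, ["v1", "v2"])[0]
        assert rep.rate == 1.0

    def test_missing_variant_denominator_policy(self):
        ref = make_sumstats("T", "ref", ["v1", "v2"], [0.2, 0.2], [0.02, 0.02])
        tgt = make_sumstats("T", "tgt", ["v1"], [0.2], [0.02])
        kept = loci.replication_rates(ref, {"t": tgt}, ["v1", "v2"],
                                      drop_missing=True)[0]
        strict = loci.replication_rates(ref, {"t": tgt}, ["v1", "v2"],
                                        drop_missing=False)[0]
        assert (kept.n_significant, kept.n_replicated) == (1, 1)
        assert (strict.n_significant, strict.n_replicated) == (2, 1)

    def test_two_regimes_by_simulation(self):
        """Shared architecture, equal n: median replication >= 0.9. Cohort-
        specific architecture: rate collapses to the directional null ~0.025."""
        rates_shared, rates_specific = [], []
        for s in range(50):
            ld = sg.ar1_ld_matrix(80, 0.8)
            eaf = np.full(80, 0.3)
            vid = ld.variant_ids[40]
            shared = sg.TrueArchitecture(causal_effects={vid: 0.12})
            a = sg.simulate_cohort_sumstats(ld, shared, 20000, eaf, seed=3 * s)
            b = sg.simulate_cohort_sumstats(ld, shared, 20000, eaf, seed=3 * s + 1)
            sig = a.records.loc[a.records["P"] < 5e-8, "SNP"].tolist()
            if sig:
                rates_shared.append(
                    loci.replication_rates(a, {"b": b}, sig)[0].rate)
            only_a = sg.TrueArchitecture(causal_effects={vid: 0.12},
                                         cohort_specific={vid: {"cohortA"}})
            a2 = sg.simulate_cohort_sumstats(ld, only_a, 20000, eaf,
                                             seed=3 * s, cohort_id="cohortA")
            b2 = sg.simulate_cohort_sumstats(ld, only_a, 20000, eaf,
                                             seed=3 * s + 2, cohort_id="cohortB")
            sig2 = a2.records.loc[a2.records["P"] < 5e-8, "SNP"].tolist()
            if sig2:
                rates_specific.append(
                    loci.replication_rates(a2, {"b": b2}, sig2)[0].rate)
        assert np.median(rates_shared) >= 0.9
        assert np.mean(rates_specific) < 0.15


class TestCallLoci:
    def test_every_significant_variant_assigned_once(self, small_panel_config):
        from cytogen.meta import meta_analyze

        panel = sg.simulate_panel(small_panel_config)
        cohorts = ["YFS_FINRISK", "SCALLOP", "DECODE"]
        mdf = meta_analyze({c: panel.sumstats[("CYT1", c)] for c in cohorts},
                           cohorts)
        window = None
        for _, row in panel.gene_panel.iterrows():
            if row["cytokine_id"] == "CYT1":
                from cytogen.sumstats_io import gene_window_1based
                window = gene_window_1based(row)
        lcs = loci.call_loci(mdf, panel.ld, window, trait_id="CYT1")
        assert len(lcs) >= 1
        labels = [lc.label for lc in lcs]
        assert labels.count("cis") + labels.count("trans") == len(labels)
        # the planted cis signal must surface as a cis locus
        assert "cis" in labels
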