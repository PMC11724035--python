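"""MR estimators, instrument selection, Steiger, FDR, network and screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cytogen import mr
from cytogen import synth_gwas as sg

from conftest import make_sumstats, single_cohort_meta
from oracles import brute_force_bh, weighted_median_reference


def _harm(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    m = len(bx)
    return pd.DataFrame({
        "SNP": [f"v{i}" for i in range(m)], "CHR": "1",
        "BP": np.arange(m) * 1000, "EA": "A", "OA": "G",
        "eaf_exp": 0.3, "eaf_out": 0.3,
        "beta_x": bx, "se_x": np.full(m, 0.01) if sx is None else np.asarray(sx),
        "p_x": 1e-6, "n_x": 1e4,
        "beta_y": np.asarray(by, float), "se_y": np.asarray(sy, float),
        "p_y": 0.5, "n_y": 1e5,
    })


class TestWaldRatio:
    def test_arithmetic(self):
        est = mr.wald_ratio(0.2, 0.1, 0.05)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.25)

    def test_zero_outcome(self):
        assert mr.wald_ratio(0.2, 0.0, 0.05).beta == 0.0

    def test_joint_sign_flip_invariance(self):
        a = mr.wald_ratio(0.2, 0.1, 0.05)
        b = mr.wald_ratio(-0.2, -0.1, 0.05)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_zero_exposure_error(self):
        with pytest.raises(ValueError):
            mr.wald_ratio(0.0, 0.1, 0.05)


class TestIVW:
    def test_two_row_example(self):
        est = mr.ivw_fixed(_harm([0.2, 0.4], [0.1, 0.18], [0.05, 0.05]))
        assert est.beta == pytest.approx(0.46, abs=1e-4)
        assert est.se == pytest.approx(0.1118, abs=1e-4)

    def test_exact_proportionality(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = mr.ivw_fixed(_harm(bx, 0.7 * bx, [0.05] * 3))
        assert est.beta == pytest.approx(0.7, rel=1e-12)

    def test_single_instrument_falls_back_to_wald(self):
        est = mr.ivw_fixed(_harm([0.2], [0.1], [0.05]))
        assert est.method == "wald"
        assert est.beta == pytest.approx(0.5)

    def test_joint_sign_flip_invariance(self):
        h = _harm([0.2, -0.4], [0.1, -0.18], [0.05, 0.05])
        h2 = h.copy()
        h2[["beta_x", "beta_y"]] = -h2[["beta_x", "beta_y"]]
        assert mr.ivw_fixed(h).beta == pytest.approx(mr.ivw_fixed(h2).beta)

    def test_calibration(self):
        """theta=0.3, 20 strong instruments: mean within ±0.02 and 95% CI
        coverage in [0.93, 0.97] over 500 sims; type-I in [0.03, 0.07] at
        theta=0."""
        rng = np.random.default_rng(101)
        bx_true = rng.uniform(0.05, 0.15, 20)
        se_x = np.full(20, 0.003)
        se_y = np.full(20, 0.01)
        est, cover, rej_null = [], 0, 0
        n_sims = 500
        for s in range(n_sims):
            bx = bx_true + se_x * rng.standard_normal(20)
            by = 0.3 * bx_true + se_y * rng.standard_normal(20)
            e = mr.ivw_fixed(_harm(bx, by, se_y, se_x))
            est.append(e.beta)
            cover += abs(e.beta - 0.3) < 1.959963984540054 * e.se
            by0 = se_y * rng.standard_normal(20)
            e0 = mr.ivw_fixed(_harm(bx, by0, se_y, se_x))
            rej_null += e0.pvalue < 0.05
        assert abs(np.mean(est) - 0.3) < 0.02
        assert 0.93 <= cover / n_sims <= 0.97
        assert 0.03 <= rej_null / n_sims <= 0.07


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        est = mr.egger(_harm(bx, 0.05 + 0.3 * bx, [0.05] * 4))
        assert est.egger_intercept == pytest.approx(0.05, abs=1e-10)
        assert est.beta == pytest.approx(0.3, abs=1e-10)

    def test_too_few_instruments(self):
        assert mr.egger(_harm([0.1, 0.2], [0.1, 0.2], [0.05, 0.05])) is None

    def test_orientation_rule(self):
        """Rows are flipped to beta_x >= 0 first, so a mixed-sign input equals
        its pre-oriented version."""
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = 0.05 * np.sign(bx) + 0.3 * bx  # pleiotropy follows orientation
        est = mr.egger(_harm(bx, by, [0.05] * 4))
        est2 = mr.egger(_harm(np.abs(bx), 0.05 + 0.3 * np.abs(bx), [0.05] * 4))
        assert est.beta == pytest.approx(est2.beta, abs=1e-10)
        assert est.egger_intercept == pytest.approx(est2.egger_intercept, abs=1e-10)

    def test_intercept_type_i_calibration(self):
        """Balanced pleiotropy: intercept test rejects at ~5% (2000 reps)."""
        rng = np.random.default_rng(202)
        rej = 0
        n_reps = 2000
        for _ in range(n_reps):
            bx = rng.uniform(0.05, 0.2, 20)
            by = 0.2 * bx + 0.01 * rng.standard_normal(20)
            if mr.egger(_harm(bx, by, [0.01] * 20)).intercept_p < 0.05:
                rej += 1
        assert 0.03 <= rej / n_reps <= 0.07

    def test_intercept_power_under_directional_pleiotropy(self):
        """+0.05 on every outcome beta, 20 instruments, small se: intercept
        detected in >=80% of reps (power pre-computed at these settings)."""
        rng = np.random.default_rng(203)
        hits = 0
        for _ in range(200):
            bx = rng.uniform(0.05, 0.2, 20)
            by = 0.05 + 0.2 * bx + 0.01 * rng.standard_normal(20)
            hits += mr.egger(_harm(bx, by, [0.01] * 20)).intercept_p < 0.05
        assert hits / 200 >= 0.8


class TestWeightedMedian:
    def test_middle_ratio(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.4, 0.5, 10.0])
        est = mr.weighted_median(_harm(bx, by, [1.0] * 3), seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-9)

    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = mr.weighted_median(_harm(bx, 0.4 * bx, [0.001] * 3), seed=1)
        assert est.beta == pytest.approx(0.4, rel=1e-6)
        assert est.se < 0.05

    def test_matches_reference_interpolation(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.1, 0.3, 9)
        by = rng.normal(0.2, 0.1, 9) * bx
        sy = rng.uniform(0.01, 0.05, 9)
        est = mr.weighted_median(_harm(bx, by, sy), seed=0)
        want = weighted_median_reference(by / bx, bx ** 2 / sy ** 2)
        assert est.beta == pytest.approx(want, rel=1e-9)

    def test_robust_to_30pct_invalid(self):
        """30% of instruments carry inflated ratios: weighted median stays
        within ±0.03 of theta=0.3 over 500 reps while IVW is biased upward."""
        rng = np.random.default_rng(303)
        wm_est, ivw_est = [], []
        for _ in range(500):
            bx = rng.uniform(0.1, 0.3, 20)
            by = 0.3 * bx + 0.005 * rng.standard_normal(20)
            by[:6] += 0.15 * bx[:6]  # invalid: ratio inflated to ~0.45
            h = _harm(bx, by, [0.005] * 20)
            wm_est.append(mr.weighted_median(h, n_boot=20, seed=1).beta)
            ivw_est.append(mr.ivw_fixed(h).beta)
        assert abs(np.mean(wm_est) - 0.3) < 0.03
        assert np.mean(ivw_est) > 0.33


class TestSteiger:
    @pytest.mark.parametrize("bx,by,kept", [
        (0.10, 0.20, False),
        (0.20, 0.10, True),
        (0.15, 0.15, True),  # equality kept (strict inequality drops)
    ])
    def test_rule(self, bx, by, kept):
        h = _harm([bx], [by], [0.01])
        out, dropped = mr.steiger_filter(h)
        assert (len(out) == 1) is kept
        assert (dropped == ["v0"]) is not kept


class TestBH:
    def test_equal_spacing_quadruple(self):
        np.testing.assert_allclose(mr.bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p(self):
        assert mr.bh_fdr([0.37])[0] == pytest.approx(0.37)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=30))
    def test_matches_oracle_and_statsmodels(self, ps):
        q = mr.bh_fdr(ps)
        np.testing.assert_allclose(q, brute_force_bh(ps), rtol=1e-12)
        np.testing.assert_allclose(
            q, multipletests(ps, method="fdr_bh")[1], rtol=1e-9)
        assert (q >= np.asarray(ps) - 1e-15).all()


class TestInstrumentSelection:
    def _meta(self, ld, pvals):
        from scipy import stats as ss
        z = ss.norm.isf(np.asarray(pvals) / 2)
        return pd.DataFrame({"SNP": ld.variant_ids, "CHR": ld.chrom,
                             "BP": ld.positions, "P": pvals})

    def test_window_p_and_clump(self):
        ld = sg.ar1_ld_matrix(5, 0.0, start_pos=1_000_000, spacing=1000)
        df = self._meta(ld, [1e-6, 0.5, 1e-7, 0.5, 0.5])
        got = mr.select_cis_instruments(df, ("1", 1_000_000, 1_005_000),
                                        sg.LDReference([ld]))
        assert set(got) == {ld.variant_ids[0], ld.variant_ids[2]}

    def test_correlated_pair_keeps_smaller_p(self):
        ld = sg.ar1_ld_matrix(2, 0.8, start_pos=1_000_000, spacing=1000)
        df = self._meta(ld, [1e-6, 1e-8])
        got = mr.select_cis_instruments(df, ("1", 1_000_000, 1_001_000),
                                        sg.LDReference([ld]))
        assert got == [ld.variant_ids[1]]

    def test_boundary_p_excluded(self):
        ld = sg.ar1_ld_matrix(1, 0.0, start_pos=1_000_000)
        df = self._meta(ld, [5e-5])
        got = mr.select_cis_instruments(df, ("1", 1_000_000, 1_000_001),
                                        sg.LDReference([ld]))
        assert got == []


def _network_world(seed, theta=0.4, n_cyt=6):
    """Simulate a 6-cytokine world where CYT1 causally raises CYT2."""
    cfg = sg.SimConfig(
        n_variants=100, seed=seed,
        sample_sizes={"POOL": 60000},
        panel_overlap={f"CYT{i + 1}": ["POOL"] for i in range(n_cyt)},
        cis_effect=0.15,
        trans_effects={"CYT2": [("CYT1", theta * 0.15)]})
    panel = sg.simulate_panel(cfg)
    from cytogen.sumstats_io import gene_window_1based
    windows = {r["cytokine_id"]: gene_window_1based(r)
               for _, r in panel.gene_panel.iterrows()}
    metas = {c: single_cohort_meta(panel.sumstats[(c, "POOL")])
             for c in windows}
    from cytogen.meta import meta_to_sumstats
    sets = {c: meta_to_sumstats(metas[c], c) for c in metas}
    return panel, metas, sets, windows


class TestNetwork:
    def test_planted_edge_recovered_with_direction(self):
        """CYT1 -> CYT2 (theta=0.4) is significant and CYT2 -> CYT1 is not,
        after Steiger filtering, in >=90% of seeds (30 seeds here; the
        acceptance suite runs 100)."""
        ok = 0
        n_seeds = 30
        for s in range(n_seeds):
            panel, metas, sets, windows = _network_world(1000 + s)
            edges = mr.mr_network(metas, sets, windows, panel.ld)
            prim = edges[edges["method"].isin(["ivw_fe", "wald"])].set_index(
                ["exposure", "outcome"])
            fwd = prim.loc[("CYT1", "CYT2")]
            rev = prim.loc[("CYT2", "CYT1")]
            ok += (fwd["q"] < 0.05) and not (rev["q"] < 0.05)
        assert ok / n_seeds >= 0.9

    def test_shared_instruments_skip_pair(self):
        panel, metas, sets, windows = _network_world(55)
        # give the outcome the exposure's meta results and window: its own
        # instrument list is then identical, so every variant is excluded
        metas2 = {"CYT1": metas["CYT1"], "CYT2": metas["CYT1"].copy()}
        windows = {"CYT1": windows["CYT1"], "CYT2": windows["CYT1"]}
        edges = mr.mr_network(metas2, sets, windows, panel.ld)
        row = edges[(edges["exposure"] == "CYT1") & (edges["outcome"] == "CYT2")]
        assert (row["status"] == "no_instruments").all()


class TestDiseaseScreen:
    def test_planted_effect_recovered(self):
        """theta=0.3 for one cytokine-disease pair among nulls: recovered at
        FDR<0.05 within ±3 SE in >=90% of seeds (30 seeds here; acceptance
        runs 100)."""
        ok = 0
        n_seeds = 30
        for s in range(n_seeds):
            panel, metas, sets, windows = _network_world(2000 + s, theta=0.0)
            eff = sg.marginal_effects(panel.ld, panel.truths["CYT3"])
            dis = {
                "DIS1": sg.simulate_disease_gwas(
                    panel.ld, eff, 0.3, 20000, 180000, seed=s, eaf=panel.eaf,
                    trait_id="DIS1"),
                "DIS2": sg.simulate_disease_gwas(
                    panel.ld, {}, 0.0, 20000, 180000, seed=10_000 + s,
                    eaf=panel.eaf, trait_id="DIS2"),
            }
            scr = mr.disease_screen(metas, dis, windows, panel.ld)
            prim = scr[scr["method"].isin(["ivw_fe", "wald"])].set_index(
                ["exposure", "outcome"])
            hit = prim.loc[("CYT3", "DIS1")]
            ok += (hit["q"] < 0.05) and abs(hit["beta"] - 0.3) < 3 * hit["se"]
        assert ok / n_seeds >= 0.9

    def test_or_ci_definition(self):
        panel, metas, sets, windows = _network_world(77)
        dis = {"DIS1": sg.simulate_disease_gwas(
            panel.ld, {}, 0.0, 20000, 180000, seed=7, eaf=panel.eaf)}
        scr = mr.disease_screen(metas, dis, windows, panel.ld)
        est = scr.dropna(subset=["beta"])
        np.testing.assert_allclose(est["odds_ratio"], np.exp(est["beta"]))
        np.testing.assert_allclose(
            est["or_ci_low"], np.exp(est["beta"] - 1.959963984540054 * est["se"]))
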