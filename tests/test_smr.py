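import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp
from scipy import stats

from momics_smr import simulate as sim
from momics_smr import smr
from momics_smr.smr import (
    LayerThresholds,
    UndefinedRatioError,
    bh_fdr,
    heidi_test,
    ratio_estimate,
    run_layer,
    satterthwaite_pvalue,
    select_instrument,
    smr_statistic,
    smr_test,
)
from momics_smr.sumstats_io import AssocDataset, LDMatrix, ProbeAnnotation

from conftest import make_stat


class TestSelectInstrument:
    probe = ProbeAnnotation("g", "g", "1", 1_500, 2_500, "expression")

    def test_minimum_p_wins(self):
        ds = AssocDataset("e", "quantitative", [
            make_stat("rs1", pos=1000, p=4e-8),
            make_stat("rs2", pos=2000, ea="C", oa="T", p=6e-8),
        ])
        top = select_instrument(ds, self.probe, window=(1, 10_000))
        assert top.snp_id == "rs1"

    def test_none_when_no_genome_wide_hit(self):
        ds = AssocDataset("e", "quantitative", [make_stat("rs1", pos=1000, p=5e-8)])
        assert select_instrument(ds, self.probe, window=(1, 10_000)) is None

    def test_tie_broken_by_distance_then_id(self):
        # probe midpoint = 2000
        ds = AssocDataset("e", "quantitative", [
            make_stat("rsA", pos=3000, p=1e-9),
            make_stat("rsB", pos=2100, ea="C", oa="T", p=1e-9),
        ])
        assert select_instrument(ds, self.probe, window=(1, 10_000)).snp_id == "rsB"
        ds2 = AssocDataset("e", "quantitative", [
            make_stat("rsD", pos=1900, p=1e-9),
            make_stat("rsC", pos=2100, ea="C", oa="T", p=1e-9),
        ])
        assert select_instrument(ds2, self.probe, window=(1, 10_000)).snp_id == "rsC"

    def test_window_respected(self):
        ds = AssocDataset("e", "quantitative", [make_stat("rs1", pos=50_000, p=1e-20)])
        assert select_instrument(ds, self.probe, window=(1, 10_000)) is None


class TestSMRTest:
    def test_ratio(self):
        exp = make_stat(beta=0.1, se=0.02)
        out = make_stat(beta=0.2, se=0.02)
        res = smr_test(exp, out)
        assert res.b_xy == pytest.approx(2.0)
        assert res.b_xy == out.beta / exp.beta  # exact identity

    def test_t_smr_closed_form(self):
        assert smr_statistic(10.0, 5.0) == pytest.approx(100 * 25 / 125)
        assert smr_statistic(10.0, 5.0) == pytest.approx(20.0)

    def test_p_smr_chi2_tail_oracle(self):
        # Independent oracle: chi2(1) upper tail at T equals the two-sided
        # normal tail at sqrt(T).
        exp = make_stat(beta=0.2, se=0.02)   # z = 10
        out = make_stat(beta=0.1, se=0.02)   # z = 5
        res = smr_test(exp, out)
        t = smr_statistic(10.0, 5.0)
        assert res.p_smr == pytest.approx(2 * stats.norm.sf(np.sqrt(t)), rel=1e-10)

    def test_null_outcome(self):
        exp = make_stat(beta=0.1, se=0.02)
        out = make_stat(beta=0.0, se=0.02, p=1.0)
        res = smr_test(exp, out)
        assert res.b_xy == 0.0
        assert res.p_smr == 1.0

    def test_zero_exposure_raises(self):
        with pytest.raises(UndefinedRatioError):
            ratio_estimate(0.0, 0.02, 0.1, 0.02)

    def test_delta_method_se(self):
        b_zx, se_zx, b_zy, se_zy = 0.1, 0.02, 0.2, 0.03
        b_xy, se_xy = ratio_estimate(b_zx, se_zx, b_zy, se_zy)
        expected = np.sqrt((b_zy**2 / b_zx**2) * (se_zy**2 / b_zy**2 + se_zx**2 / b_zx**2))
        assert se_xy == pytest.approx(expected, rel=1e-12)

    def test_or_and_ci_for_binary_outcome(self):
        exp = make_stat(beta=0.1, se=0.02)
        out = make_stat(beta=0.05, se=0.02)
        res = smr_test(exp, out, binary_outcome=True)
        assert res.or_xy == pytest.approx(np.exp(res.b_xy))
        assert res.or_ci_low == pytest.approx(np.exp(res.b_xy - 1.959963984540054 * res.se_xy))

    @given(
        c=st_hyp.floats(min_value=0.1, max_value=10).filter(lambda x: abs(x) > 1e-6),
        b_zx=st_hyp.floats(min_value=-1, max_value=1).filter(lambda x: abs(x) > 1e-3),
        b_zy=st_hyp.floats(min_value=-1, max_value=1),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, c, b_zx, b_zy):
        exp = make_stat(beta=b_zx, se=0.02)
        out = make_stat(beta=b_zy, se=0.03)
        exp_scaled = make_stat(beta=c * b_zx, se=c * 0.02)
        r1 = smr_test(exp, out)
        r2 = smr_test(exp_scaled, out)
        assert r2.p_smr == pytest.approx(r1.p_smr, rel=1e-9)
        assert r2.b_xy == pytest.approx(r1.b_xy / c, rel=1e-9)

    def test_sign_antisymmetry(self):
        exp = make_stat(beta=0.1, se=0.02)
        out = make_stat(beta=0.05, se=0.02)
        r1 = smr_test(exp, out)
        r2 = smr_test(exp, out.flipped())
        assert r2.b_xy == pytest.approx(-r1.b_xy)
        assert r2.p_smr == pytest.approx(r1.p_smr, rel=1e-12)


class TestBHFDR:
    def test_textbook_example(self):
        # Brute-force oracle gives q = [0.04, 0.04, 0.04, 0.04]
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_against_brute_force_oracle(self):
        def brute(p):
            p = np.asarray(p)
            m = len(p)
            q = np.empty(m)
            for i in range(m):
                # min over all j with p_j >= p_i of m * p_j / rank(p_j)
                cands = []
                for j in range(m):
                    if p[j] >= p[i]:
                        rank = np.sum(p <= p[j])
                        cands.append(m * p[j] / rank)
                q[i] = min(min(cands), 1.0)
            return q

        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 25))
            np.testing.assert_allclose(bh_fdr(p), brute(p), atol=1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    def test_order_preserving(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1, 50)
        q = bh_fdr(p)
        order_p = np.argsort(p)
        assert np.all(np.diff(q[order_p]) >= -1e-15)


class TestHEIDI:
    def _pair_with_duplicate_top(self):
        """Top SNP plus one extra SNP in perfect LD carrying identical stats."""
        recs_e = [
            make_stat("rs_top", pos=1000, beta=0.2, se=0.02),
            make_stat("rs_dup", pos=2000, ea="C", oa="T", beta=0.2, se=0.02),
        ]
        recs_o = [
            make_stat("rs_top", pos=1000, beta=0.1, se=0.02),
            make_stat("rs_dup", pos=2000, ea="C", oa="T", beta=0.1, se=0.02),
        ]
        exp = AssocDataset("e", "quantitative", recs_e)
        out = AssocDataset("o", "quantitative", recs_o)
        ld = LDMatrix(["rs_top", "rs_dup"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        return exp, out, ld

    def test_perfect_ld_duplicate_excluded_by_default_r2max(self):
        exp, out, ld = self._pair_with_duplicate_top()
        p, k = heidi_test(exp, out, ld, "rs_top")
        assert p is None and k == 0  # r^2 = 1 > 0.9

    def test_perfect_ld_degenerate_with_lifted_r2max(self):
        exp, out, ld = self._pair_with_duplicate_top()
        p, k = heidi_test(exp, out, ld, "rs_top", r2_max=1.0)
        assert k == 1
        assert p == pytest.approx(1.0)

    def test_no_eligible_snps_returns_none(self):
        exp = AssocDataset("e", "quantitative", [make_stat("rs_top", beta=0.2, se=0.02)])
        ld = LDMatrix(["rs_top"], np.array([[1.0]]))
        p, k = heidi_test(exp, exp, ld, "rs_top")
        assert p is None and k == 0

    def test_weak_exposure_snps_ineligible(self):
        recs = [
            make_stat("rs_top", pos=1000, beta=0.2, se=0.02),
            make_stat("rs_weak", pos=2000, ea="C", oa="T", beta=0.01, se=0.02),
        ]
        ds = AssocDataset("e", "quantitative", recs)
        ld = LDMatrix(["rs_top", "rs_weak"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        p, k = heidi_test(ds, ds, ld, "rs_top")
        assert p is None and k == 0

    def test_satterthwaite_vs_monte_carlo_oracle(self):
        # Null distribution of sum z_i^2, z ~ N(0, C): compare the
        # two-moment approximation against direct simulation.
        rng = np.random.default_rng(11)
        a = rng.standard_normal((4, 4))
        c = a @ a.T
        d = np.sqrt(np.diag(c))
        corr = c / np.outer(d, d)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(4))
        draws = chol @ rng.standard_normal((4, 200_000))
        t_null = np.sum(draws**2, axis=0)
        for t_obs in (2.0, 6.0, 12.0):
            p_mc = np.mean(t_null >= t_obs)
            p_sat = satterthwaite_pvalue(t_obs, corr)
            assert abs(p_sat - p_mc) < 0.02

    def test_heidi_detects_linkage(self, std_region):
        region = sim.simulate_region(sim.RegionSpec(m_snps=41, rho=0.6, seed=0))
        sc = sim.ScenarioSpec("H3", n1=50_000, n2=50_000,
                              causal_index_trait1=20, causal_index_trait2=21)
        rej = 0
        for s in range(100):
            t1, t2 = sim.simulate_sumstats(region, sc, seed=s)
            top = max(t1.records, key=lambda r: abs(r.z))
            p, _ = heidi_test(t1, t2, region.ld, top.snp_id)
            if p is not None and p < 0.05:
                rej += 1
        assert rej >= 50

    def test_missing_top_snp_raises(self, std_region):
        sc = sim.ScenarioSpec("H0", n1=1000, n2=1000)
        t1, t2 = sim.simulate_sumstats(std_region, sc, seed=0)
        with pytest.raises(ValueError):
            heidi_test(t1, t2, std_region.ld, "rs_nonexistent")


class TestRunLayer:
    def _layer_inputs(self, std_region, theta_ed, seed):
        chain = sim.ChainSpec(theta_me=-0.5, theta_ep=0.6, theta_ed=theta_ed,
                              causal_index=20, n_expr=50_000)
        layers = sim.simulate_chain(std_region, chain, seed=seed)
        probe = sim.default_probe(std_region, "expression")
        return [probe], {probe.probe_id: layers["expression"]}, layers["disease"]

    def test_flag_rules(self):
        thr = LayerThresholds()
        assert smr._flag(0.01, 0.2, thr) == "significant"
        assert smr._flag(0.01, 0.03, thr) == "pleiotropic"
        assert smr._flag(0.06, 0.2, thr) == "not_significant"
        assert smr._flag(0.01, None, thr) == "heidi_not_evaluable"

    def test_true_causal_probe_significant(self, std_region):
        hits = 0
        n_seeds = 50
        for s in range(n_seeds):
            probes, exposure, disease = self._layer_inputs(std_region, 0.4, s)
            df = run_layer(probes, exposure, disease,
                           ld_store=lambda pid: std_region.ld, outcome_id="disease")
            assert len(df) == 1
            row = df.iloc[0]
            if row.q_smr < 0.05 and (np.isnan(row.p_heidi) or row.p_heidi > 0.05):
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_output_columns(self, std_region):
        probes, exposure, disease = self._layer_inputs(std_region, 0.4, 0)
        df = run_layer(probes, exposure, disease, ld_store=lambda pid: std_region.ld)
        assert list(df.columns) == smr.RESULT_COLUMNS
        assert df.iloc[0]["or_xy"] == pytest.approx(np.exp(df.iloc[0]["b_xy"]))

    def test_probe_without_instrument_dropped(self, std_region):
        sc = sim.ScenarioSpec("H0", n1=1000, n2=1000)
        t1, t2 = sim.simulate_sumstats(std_region, sc, seed=1)
        probe = sim.default_probe(std_region, "expression")
        df = run_layer([probe], {probe.probe_id: t1}, t2,
                       ld_store=lambda pid: std_region.ld)
        assert len(df) == 0
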