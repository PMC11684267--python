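import numpy as np
import pytest
from scipy import stats

from drugmr import sim, smr
from tests.conftest import make_smr_region


class TestSMRStatistic:
    def test_null_gwas_gives_p_one(self):
        assert smr.smr_statistic(10.0, 0.0) == 0.0

    def test_worked_ratio(self):
        # chi2_1 tail oracle for T = 400/104
        t = smr.smr_statistic(10.0, 2.0)
        assert t == pytest.approx(400.0 / 104.0)
        assert stats.chi2.sf(t, 1) == pytest.approx(0.0498, abs=2e-4)

    def test_strong_qtl_limit(self):
        t = smr.smr_statistic(1e6, 2.0)
        assert t == pytest.approx(4.0, rel=1e-6)

    def test_symmetry(self):
        assert smr.smr_statistic(3.0, 7.0) == pytest.approx(smr.smr_statistic(7.0, 3.0))

    def test_bounded_by_weaker_leg(self):
        rng = np.random.default_rng(0)
        z1, z2 = rng.normal(0, 3, 10_000), rng.normal(0, 3, 10_000)
        t = (z1**2 * z2**2) / (z1**2 + z2**2)
        for a, b, tt in zip(z1, z2, t):
            assert tt <= min(a**2, b**2) + 1e-12


class TestSMRTest:
    def test_record_fields_consistent(self):
        qtl, gwas, ld = make_smr_region(0)
        rec = smr.smr_test(qtl, gwas, "G")
        assert rec.b_smr == pytest.approx(rec.b_gwas / rec.b_qtl)
        z_q, z_g = rec.b_qtl / rec.se_qtl, rec.b_gwas / rec.se_gwas
        assert rec.se_smr == pytest.approx(
            abs(rec.b_smr) * np.sqrt(1 / z_q**2 + 1 / z_g**2)
        )
        # the test is never more significant than its weaker leg
        assert rec.p_smr >= min(rec.p_qtl, rec.p_gwas) - 1e-12

    def test_top_snp_is_strongest_qtl(self):
        qtl, gwas, ld = make_smr_region(1)
        rec = smr.smr_test(qtl, gwas)
        assert rec.top_snp == qtl.loc[(qtl["beta"] / qtl["se"]).abs().idxmax(), "variant_id"]

    def test_null_p_uniform(self):
        ps = []
        for s in range(400):
            qtl, gwas, _ = make_smr_region(10_000 + s, null_outcome=True, n_snps=10)
            ps.append(smr.smr_test(qtl, gwas).p_smr)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestHEIDI:
    def test_perfect_ld_identical_ratios_p_one(self):
        m = 6
        ld = sim.simulate_ld_matrix(m, [m], 0.999999)
        # construct harmonizable tables directly with identical SMR ratios
        truth = sim.SimTruth(seed=1, n_exposure=50_000, n_outcome=500_000)
        qtl = sim.simulate_qtl_sumstats(
            truth, ld, 1, causal_indices=[0], causal_effects=[0.8], sampling_noise=False
        )
        truth2 = sim.SimTruth(causal_beta=0.2, seed=1, n_exposure=50_000, n_outcome=500_000)
        gwas = sim.simulate_outcome_gwas(truth2, qtl, ld, sampling_noise=False)
        p, n_used = smr.heidi_test(qtl, gwas, ld)
        assert n_used == m - 1
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_too_few_eligible_snps_undefined(self):
        qtl, gwas, ld = make_smr_region(2, n_snps=4, rho=0.05, causal_index=1)
        p, n_used = smr.heidi_test(qtl, gwas, ld, min_snps=3)
        if n_used < 3:
            assert p is None

    def test_relabeling_invariance(self):
        qtl, gwas, ld = make_smr_region(3)
        p1, _ = smr.heidi_test(qtl, gwas, ld)
        # relabel non-top variants (reverse row order, consistent LD relabel)
        order = list(range(len(qtl)))[::-1]
        qtl2 = qtl.iloc[order].reset_index(drop=True)
        gwas2 = gwas.iloc[order].reset_index(drop=True)
        p2, _ = smr.heidi_test(qtl2, gwas2, ld)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_calibration_single_causal(self):
        ps = []
        for s in range(200):
            qtl, gwas, ld = make_smr_region(20_000 + s)
            p, _ = smr.heidi_test(qtl, gwas, ld)
            if p is not None:
                ps.append(p)
        rej = np.mean(np.array(ps) < 0.01)
        assert 0.0 <= rej <= 0.05  # near-nominal at the 0.01 level

    def test_linkage_lowers_p(self):
        singles, linked = [], []
        for s in range(100):
            qtl, gwas, ld = make_smr_region(30_000 + s)
            p1, _ = smr.heidi_test(qtl, gwas, ld)
            # same region, outcome driven by a *different* variant in weak LD
            qtl2, gwas2, ld2 = make_smr_region(30_000 + s, null_outcome=True)
            direct = np.zeros(len(ld2.variant_ids))
            direct[2] = 0.05
            gwas2 = gwas2.copy()
            gwas2["beta"] = gwas2["beta"] + ld2.r @ direct
            gwas2["pval"] = 2 * stats.norm.sf(np.abs(gwas2["beta"] / gwas2["se"]))
            p2, _ = smr.heidi_test(qtl2, gwas2, ld2)
            singles.append(p1)
            linked.append(p2)
        assert np.median(linked) < np.median(singles)


class TestThreeStep:
    def _chain_region(self, b_me, b_eo, seed=5, noise=False):
        ld = sim.simulate_ld_matrix(20, [20], 0.8)
        truth = sim.SimTruth(
            mediation_chain=(b_me, b_eo), n_exposure=50_000, n_outcome=500_000, seed=seed
        )
        return sim.simulate_mediation_region(
            truth, ld, n_causal=1, causal_indices=[8], causal_effects=[0.8],
            sampling_noise=noise,
        ) + (ld,)

    def test_consistent_chain_verdict_true(self):
        mqtl, eqtl, gwas, ld = self._chain_region(-1.0, -0.3)
        verdict = smr.three_step_smr(eqtl, mqtl, gwas, ld, "GENE", "CPG")
        assert verdict.verdict is True
        assert verdict.sign_chain_consistent is True
        # (-) x (-) = + matches the methylation->outcome sign
        assert np.sign(verdict.step3.b_smr) * np.sign(verdict.step1.b_smr) == np.sign(
            verdict.step2.b_smr
        )

    def test_weak_step2_fails(self):
        mqtl, eqtl, gwas, ld = self._chain_region(-1.0, -0.3)
        # outcome unrelated to methylation: replace gwas with a null table
        truth0 = sim.SimTruth(seed=6, n_exposure=50_000, n_outcome=500_000)
        gwas0 = sim.simulate_outcome_gwas(truth0, mqtl, ld, seed=99)
        verdict = smr.three_step_smr(eqtl, mqtl, gwas0, ld)
        assert verdict.verdict is False

    def test_subthreshold_gwas_significance_fails(self):
        mqtl, eqtl, gwas, ld = self._chain_region(-1.0, -0.3)
        # shrink outcome effects so the top-SNP GWAS p is ~1e-6 (> 5e-8)
        gwas = gwas.copy()
        z_target = stats.norm.isf(0.5e-6)
        top = gwas["beta"].abs().idxmax()
        scale = z_target * gwas.loc[top, "se"] / abs(gwas.loc[top, "beta"])
        gwas["beta"] = gwas["beta"] * scale
        gwas["pval"] = 2 * stats.norm.sf(np.abs(gwas["beta"] / gwas["se"]))
        verdict = smr.three_step_smr(eqtl, mqtl, gwas, ld)
        assert verdict.gw_significant is False
        assert verdict.verdict is False


class TestProteinConsistency:
    def _rec(self, b, p_smr=0.001, p_heidi=0.5):
        return smr.SMRRecord(
            "P", "rs1", 0.5, 0.01, 1e-30, b * 0.5, 0.01, 1e-10,
            b_smr=b, se_smr=0.1, p_smr=p_smr, p_heidi=p_heidi, n_heidi_snps=5,
        )

    def test_same_sign_true(self):
        assert smr.protein_consistency(self._rec(0.3), self._rec(0.2)) is True

    def test_opposite_sign_false(self):
        assert smr.protein_consistency(self._rec(0.3), self._rec(-0.2)) is False

    def test_nonsignificant_protein_undefined_false(self):
        assert smr.protein_consistency(self._rec(0.3), self._rec(0.2, p_smr=0.2)) is False

    def test_heidi_failure_undefined_false(self):
        assert smr.protein_consistency(self._rec(0.3), self._rec(0.2, p_heidi=0.005)) is False
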