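import numpy as np
import pytest
from scipy import stats

from drugmr import mr
from tests.conftest import make_ivw_replicate, pairs_frame


class TestWaldRatio:
    def test_zero_outcome(self):
        r = mr.wald_ratio([0.5], [0.01], [0.0], [0.05])
        assert r.beta == 0.0

    def test_delta_method(self):
        r = mr.wald_ratio([0.5], [0.01], [0.1], [0.05])
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1)

    def test_sign(self):
        r = mr.wald_ratio([-0.5], [0.01], [0.1], [0.05])
        assert r.beta == pytest.approx(-0.2)

    def test_zero_exposure_raises(self):
        with pytest.raises(ZeroDivisionError):
            mr.wald_ratio([0.0], [0.01], [0.1], [0.05])


class TestIVW:
    def test_common_ratio_recovered_q_zero(self):
        bx = np.array([0.5, 0.25, 0.4])
        by = 0.3 * bx
        r = mr.ivw_mre(bx, bx * 0, by, np.full(3, 0.05))
        assert r.beta == pytest.approx(0.3)
        assert r.cochran_q == pytest.approx(0.0, abs=1e-20)

    def test_two_snp_closed_form(self):
        # WLS through the origin: beta = sum(w bx by)/sum(w bx^2) = 0.2
        r = mr.ivw_mre([0.5, 0.25], [0, 0], [0.1, 0.05], [0.05, 0.05])
        assert r.beta == pytest.approx(0.2)
        assert r.cochran_q == pytest.approx(0.0, abs=1e-20)
        assert r.se == pytest.approx(1.0 / np.sqrt(0.3125 / 0.0025))

    def test_k1_rejected_and_routed_to_wald(self):
        with pytest.raises(ValueError):
            mr.ivw_mre([0.5], [0.01], [0.1], [0.05])
        pairs = pairs_frame([0.5], [0.01], [0.1], [0.05])
        battery = mr.run_mr_battery(pairs)
        assert battery["ivw"].method == "wald_ratio"
        direct = mr.wald_ratio([0.5], [0.01], [0.1], [0.05])
        assert battery["ivw"].beta == direct.beta
        assert battery["ivw"].se == direct.se

    def test_mre_never_tighter_than_fixed(self):
        pairs = make_ivw_replicate(0, causal_beta=0.3, pleiotropy_mode="balanced",
                                   pleiotropy_sd=0.05)
        bx, sx, by, sy, _ = mr.pairs_arrays(pairs)
        assert mr.ivw_mre(bx, sx, by, sy).se >= mr.ivw_fixed(bx, sx, by, sy).se


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        by = 0.05 + 0.3 * bx
        r = mr.egger_regression(bx, bx * 0, by, np.full(4, 0.05))
        assert r.egger_intercept == pytest.approx(0.05)
        assert r.beta == pytest.approx(0.3)

    def test_balanced_null_intercept(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.1, 0.5, 20)
        sy = np.full(20, 0.03)
        by = 0.3 * bx + rng.normal(0, 0.03, 20)
        r = mr.egger_regression(bx, bx * 0, by, sy)
        assert abs(r.egger_intercept) < 3 * r.intercept_se

    def test_singular_design_raises(self):
        bx = np.full(4, 0.3)
        with pytest.raises(np.linalg.LinAlgError):
            mr.egger_regression(bx, bx * 0, 0.3 * bx, np.full(4, 0.05))


class TestWeightedMedian:
    def test_equal_weight_ratios(self):
        r = mr.weighted_median(np.ones(3), np.full(3, 1e-9),
                               np.array([0.1, 0.2, 0.9]), np.ones(3), n_boot=50)
        assert r.beta == pytest.approx(0.2)

    def test_constant_ratio_zero_spread(self):
        bx = np.array([0.2, 0.4, 0.6])
        r = mr.weighted_median(bx, np.zeros(3), 0.3 * bx, np.full(3, 1e-12), n_boot=50)
        assert r.beta == pytest.approx(0.3)
        assert r.se == pytest.approx(0.0, abs=1e-9)

    def test_weight_concentration_limit(self):
        bx = np.array([10.0, 0.01, 0.01])
        by = np.array([5.0, 0.009, 0.002])  # ratios 0.5, 0.9, 0.2
        r = mr.weighted_median(bx, np.zeros(3), by, np.ones(3), n_boot=50)
        assert r.beta == pytest.approx(0.5, abs=0.01)


class TestWeightedMode:
    def test_majority_cluster(self):
        r = mr.weighted_mode(np.ones(4), np.full(4, 1e-9),
                             np.array([0.2, 0.2, 0.2, 5.0]), np.ones(4), n_boot=50)
        assert r.beta == pytest.approx(0.2)

    def test_symmetric_tie_breaks_to_smaller_abs(self):
        r = mr.weighted_mode(np.ones(4), np.full(4, 1e-9),
                             np.array([0.1, 0.1, 0.9, 0.9]), np.ones(4), n_boot=50)
        assert r.beta == pytest.approx(0.1)

    def test_single_cluster_with_noise_within_span(self):
        rng = np.random.default_rng(2)
        ratios = 0.3 + rng.normal(0, 0.02, 12)
        r = mr.weighted_mode(np.ones(12), np.full(12, 1e-9), ratios, np.ones(12), n_boot=50)
        assert ratios.min() <= r.beta <= ratios.max()


class TestRAPS:
    def test_matches_ivw_when_exposure_exact(self):
        rng = np.random.default_rng(3)
        bx = rng.normal(0, 0.2, 8)
        sy = np.full(8, 0.03)
        by = 0.3 * bx + rng.normal(0, 0.03, 8)
        ivw = mr.ivw_fixed(bx, bx * 0, by, sy)
        raps = mr.raps_estimate(bx, np.full(8, 1e-10), by, sy, psi="simple")
        assert raps.beta == pytest.approx(ivw.beta, abs=1e-6)

    def test_consistency_under_truth(self):
        pairs = make_ivw_replicate(7, causal_beta=0.3, k=20, n_exposure=100_000,
                                   n_outcome=100_000)
        bx, sx, by, sy, _ = mr.pairs_arrays(pairs)
        r = mr.raps_estimate(bx, sx, by, sy)
        assert abs(r.beta - 0.3) < 3 * r.se

    def test_huber_more_robust_than_simple(self):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.1, 0.5, 10)
        sy = np.full(10, 0.02)
        by = 0.3 * bx
        clean = mr.raps_estimate(bx, np.full(10, 1e-6), by, sy, psi="simple").beta
        by_out = by.copy()
        by_out[0] += 0.5
        simple = mr.raps_estimate(bx, np.full(10, 1e-6), by_out, sy, psi="simple").beta
        huber = mr.raps_estimate(bx, np.full(10, 1e-6), by_out, sy, psi="huber").beta
        assert abs(huber - clean) < abs(simple - clean)


class TestMaxLikelihood:
    def test_matches_ivw_fixed_when_exposure_exact(self):
        rng = np.random.default_rng(5)
        bx = rng.normal(0, 0.2, 8)
        sy = np.full(8, 0.03)
        by = 0.3 * bx + rng.normal(0, 0.03, 8)
        ivw = mr.ivw_fixed(bx, bx * 0, by, sy)
        ml = mr.max_likelihood(bx, np.full(8, 1e-10), by, sy)
        assert ml.beta == pytest.approx(ivw.beta, abs=1e-6)

    def test_matches_grid_search(self):
        bx = np.array([0.3, -0.2])
        sx = np.array([0.05, 0.04])
        by = np.array([0.12, -0.05])
        sy = np.array([0.03, 0.03])
        ml = mr.max_likelihood(bx, sx, by, sy)
        grid = np.linspace(-1, 1, 200_001)
        nll = [mr._profile_negloglik(b, bx, sx, by, sy) for b in grid]
        assert ml.beta == pytest.approx(grid[int(np.argmin(nll))], abs=1e-4)

    def test_null_z_controlled(self):
        zs = []
        for s in range(100):
            pairs = make_ivw_replicate(s, causal_beta=0.0, k=6)
            bx, sx, by, sy, _ = mr.pairs_arrays(pairs)
            r = mr.max_likelihood(bx, sx, by, sy)
            zs.append(r.beta / r.se)
        assert np.mean(np.abs(zs) < 3) >= 0.97


class TestLeaveOneOut:
    def test_homogeneous_no_flag(self):
        bx = np.linspace(0.2, 0.6, 5)
        loo = mr.leave_one_out(bx, bx * 0, 0.3 * bx, np.full(5, 0.05))
        assert not loo["flagged"].any()

    def test_outlier_flagged_on_omission(self):
        bx = np.linspace(0.2, 0.6, 6)
        by = 0.3 * bx
        by[2] += 1.0
        loo = mr.leave_one_out(bx, bx * 0, by, np.full(6, 0.02))
        assert loo.loc[loo["omitted"] == "v2", "flagged"].iloc[0]

    def test_refit_count(self):
        bx = np.array([0.2, 0.3, 0.4])
        loo = mr.leave_one_out(bx, bx * 0, 0.3 * bx, np.full(3, 0.05))
        assert len(loo) == 3


class TestRadial:
    def test_identical_ratios_no_outliers(self):
        bx = np.array([0.2, 0.4, 0.6])
        rep = mr.radial_outliers(bx, bx * 0, 0.3 * bx, np.full(3, 0.05))
        assert rep.outlier_ids == []
        assert rep.global_stat == pytest.approx(0.0, abs=1e-20)

    def test_displaced_variant_flagged(self):
        bx = np.linspace(0.2, 0.8, 8)
        sy = np.full(8, 0.02)
        by = 0.3 * bx
        by[3] += 10 * sy[3]
        rep = mr.radial_outliers(bx, np.full(8, 1e-6), by, sy, ids=[f"v{i}" for i in range(8)])
        assert "v3" in rep.outlier_ids

    def test_removal_reduces_q(self):
        bx = np.linspace(0.2, 0.8, 8)
        sy = np.full(8, 0.02)
        by = 0.3 * bx
        by[3] += 10 * sy[3]
        full = mr.radial_outliers(bx, np.full(8, 1e-6), by, sy)
        keep = np.arange(8) != 3
        reduced = mr.radial_outliers(bx[keep], np.full(7, 1e-6), by[keep], sy[keep])
        assert reduced.global_stat < full.global_stat


class TestPRESSO:
    def test_null_global_p_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(200):
            bx = rng.uniform(0.1, 0.5, 8)
            sx = np.full(8, 0.005)
            sy = np.full(8, 0.03)
            by = 0.3 * rng.normal(bx, sx) + rng.normal(0, 0.03, 8)
            res = mr.mr_presso(bx, sx, by, sy, n_sim=300, seed=rep)
            ps.append(res.global_pval)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_gross_outlier_detected(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.1, 0.5, 8)
        sy = np.full(8, 0.02)
        by = 0.3 * bx + rng.normal(0, 0.02, 8)
        by[0] += 0.6
        res = mr.mr_presso(bx, np.full(8, 0.005), by, sy, n_sim=1000, seed=1)
        assert "v0" in res.outlier_ids
        assert res.global_pval < 0.05

    def test_zero_sims_rejected(self):
        with pytest.raises(ValueError):
            mr.mr_presso(np.ones(4), np.ones(4), np.ones(4), np.ones(4), n_sim=0)


@pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median", "weighted_mode",
                                    "raps", "max_likelihood"])
def test_sign_and_scale_equivariance(method):
    pairs = make_ivw_replicate(11, causal_beta=0.3, k=8)
    bx, sx, by, sy, _ = mr.pairs_arrays(pairs)

    def fit(bxa, sxa):
        fns = {
            "ivw": lambda: mr.ivw_mre(bxa, sxa, by, sy),
            "egger": lambda: mr.egger_regression(bxa, sxa, by, sy),
            "weighted_median": lambda: mr.weighted_median(bxa, sxa, by, sy, n_boot=50, seed=3),
            "weighted_mode": lambda: mr.weighted_mode(bxa, sxa, by, sy, n_boot=50, seed=3),
            "raps": lambda: mr.raps_estimate(bxa, sxa, by, sy),
            "max_likelihood": lambda: mr.max_likelihood(bxa, sxa, by, sy),
        }
        return fns[method]()

    base = fit(bx, sx)
    neg = fit(-bx, sx)
    assert neg.beta == pytest.approx(-base.beta, rel=1e-5, abs=1e-8)
    scaled = fit(2.0 * bx, 2.0 * sx)
    assert scaled.beta == pytest.approx(base.beta / 2.0, rel=1e-5, abs=1e-8)
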