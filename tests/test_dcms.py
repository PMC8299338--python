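import numpy as np
import pytest

import oracles
from dcmscan.dcms import (bh_qvalues, dcms_combine, dcms_track,
                          fractional_rank_pvalues, robust_correlation_mcd,
                          robust_normal_fit, upper_tail_p)


class TestFractionalRanks:
    def test_right_tail_example(self):
        got = fractional_rank_pvalues(np.array([1.0, 2.0, 3.0]), "right")
        assert np.allclose(got, [3 / 4, 2 / 4, 1 / 4])

    def test_ties_share_ranks(self):
        for tail in ("left", "right", "two"):
            got = fractional_rank_pvalues(np.array([5.0, 5.0]), tail)
            assert got[0] == got[1]

    def test_bounds_attained(self, rng):
        v = rng.normal(size=100)
        left = fractional_rank_pvalues(v, "left")
        assert left.min() == pytest.approx(1 / 101)
        assert left.max() == pytest.approx(100 / 101)
        assert np.all((left > 0) & (left < 1))

    @pytest.mark.parametrize("tail", ["left", "right", "two"])
    def test_oracle_equivalence(self, rng, tail):
        for _ in range(30):
            v = rng.integers(0, 6, size=rng.integers(1, 25)).astype(float)
            got = fractional_rank_pvalues(v, tail)
            assert np.allclose(got, oracles.fractional_rank_p(v, tail),
                               atol=1e-12)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            fractional_rank_pvalues(np.array([]), "left")


class TestMCDCorrelation:
    def test_identical_columns_correlate_fully(self, rng):
        x = rng.normal(size=200)
        X = np.column_stack([x, x, rng.normal(size=200)])
        R, meta = robust_correlation_mcd(X, nsamp=100, seed=0)
        assert R[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_columns_near_zero(self, rng):
        X = rng.normal(size=(10_000, 3))
        R, _ = robust_correlation_mcd(X, nsamp=200, seed=1)
        off = R[np.triu_indices(3, k=1)]
        assert np.all(np.abs(off) < 0.05)

    def test_recovers_known_correlation(self, rng):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=5000)
        R, _ = robust_correlation_mcd(X, nsamp=300, seed=2)
        assert R[0, 1] == pytest.approx(0.8, abs=0.05)

    def test_agrees_with_sklearn_mincovdet(self, rng):
        """Independent cross-check of the FAST-MCD implementation."""
        from sklearn.covariance import MinCovDet

        cov = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.3], [0.0, 0.3, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=3000)
        R, _ = robust_correlation_mcd(X, alpha=0.75, nsamp=300, seed=3)
        mcd = MinCovDet(support_fraction=0.75, random_state=0).fit(X)
        S = mcd.covariance_
        sd = np.sqrt(np.diag(S))
        R_ref = S / np.outer(sd, sd)
        assert np.allclose(R, R_ref, atol=0.05)

    def test_seeded_and_reproducible(self, rng):
        X = rng.normal(size=(500, 4))
        R1, _ = robust_correlation_mcd(X, nsamp=50, seed=7)
        R2, _ = robust_correlation_mcd(X, nsamp=50, seed=7)
        assert np.array_equal(R1, R2)

    def test_properties(self, rng):
        X = rng.normal(size=(400, 5))
        R, _ = robust_correlation_mcd(X, nsamp=100, seed=4)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert np.all(np.abs(R) <= 1.0 + 1e-12)
        assert np.linalg.eigvalsh(R).min() > -1e-8

    def test_degenerate_falls_back_to_classical(self, rng, caplog):
        x = rng.normal(size=100)
        X = np.column_stack([x, 2 * x])  # rank 1: every subset singular
        R, meta = robust_correlation_mcd(X, nsamp=50, seed=5)
        assert meta["fallback_classical"]
        assert R[0, 1] == pytest.approx(1.0)


class TestDCMSCombine:
    def test_all_half_pvalues_give_zero(self):
        P = np.full((10, 5), 0.5)
        assert np.allclose(dcms_combine(P, np.eye(5)), 0.0)

    def test_identity_correlation_single_logit(self):
        P = np.array([[0.1, 0.5, 0.5, 0.5, 0.5]])
        assert dcms_combine(P, np.eye(5))[0] == pytest.approx(np.log(9.0))

    def test_identity_correlation_is_sum_of_logits(self, rng):
        P = rng.uniform(0.01, 0.99, size=(50, 5))
        want = np.log((1 - P) / P).sum(axis=1)
        assert np.allclose(dcms_combine(P, np.eye(5)), want, atol=1e-12)

    def test_full_correlation_no_double_counting(self):
        R = np.ones((5, 5))
        P = np.tile(np.array([[0.2]]), (1, 5))
        got = dcms_combine(P, R)[0]
        assert got == pytest.approx(np.log(0.8 / 0.2))

    def test_full_correlation_is_mean_logit(self, rng):
        R = np.ones((3, 3))
        P = rng.uniform(0.05, 0.95, size=(20, 3))
        want = np.log((1 - P) / P).mean(axis=1)
        assert np.allclose(dcms_combine(P, R), want, atol=1e-12)

    def test_strictly_decreasing_in_each_pvalue(self, rng):
        R = np.clip(rng.uniform(-0.5, 0.9, (5, 5)), -1, 1)
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        P = np.full((1, 5), 0.4)
        base = dcms_combine(P, R)[0]
        for t in range(5):
            P2 = P.copy()
            P2[0, t] = 0.6
            assert dcms_combine(P2, R)[0] < base

    def test_out_of_range_pvalue_is_an_error(self):
        with pytest.raises(ValueError):
            dcms_combine(np.array([[0.0, 0.5]]), np.eye(2))


class TestRobustNormalFit:
    def test_consistent_on_clean_normal(self, rng):
        x = rng.normal(size=100_000)
        mu, sigma = robust_normal_fit(x)
        assert mu == pytest.approx(0.0, abs=0.02)
        assert sigma == pytest.approx(1.0, abs=0.02)

    def test_resists_contamination(self, rng):
        x = rng.normal(size=10_000)
        xc = x.copy()
        idx = rng.choice(len(x), size=len(x) // 20, replace=False)
        xc[idx] = 100.0
        mu, _ = robust_normal_fit(xc)
        assert abs(mu) < 0.1
        assert abs(xc.mean()) > 4.0  # the plain mean is dragged

    def test_symmetric_data_location_is_median(self, rng):
        v = rng.normal(0.0, 2.0, size=2500)
        x = np.concatenate([v, -v]) + 3.0  # exactly symmetric about 3
        mu, _ = robust_normal_fit(x)
        assert mu == pytest.approx(np.median(x), abs=1e-6)

    def test_agrees_with_statsmodels_rlm(self, rng):
        import statsmodels.api as sm

        x = rng.standard_t(df=4, size=2000) + 1.5
        mu, _ = robust_normal_fit(x)
        rlm = sm.RLM(x, np.ones((len(x), 1)),
                     M=sm.robust.norms.HuberT(1.345)).fit(scale_est="mad")
        assert mu == pytest.approx(rlm.params[0], abs=5e-3)

    def test_zero_spread_is_an_error(self):
        with pytest.raises(ValueError):
            robust_normal_fit(np.ones(100))


class TestUpperTailP:
    def test_at_the_mean(self):
        assert upper_tail_p(np.array([2.0]), 2.0, 1.0)[0] == pytest.approx(0.5)

    def test_normal_quantile(self):
        p = upper_tail_p(np.array([1.959964]), 0.0, 1.0)[0]
        assert p == pytest.approx(0.025, abs=1e-6)

    def test_monotone(self, rng):
        d = np.sort(rng.normal(size=50))
        p = upper_tail_p(d, 0.0, 1.0)
        assert np.all(np.diff(p) <= 0)


class TestBHQvalues:
    def test_single_p(self):
        assert bh_qvalues(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_known_vectors(self):
        assert np.allclose(bh_qvalues(np.array([0.01, 0.02, 0.03])),
                           [0.03, 0.03, 0.03])
        assert np.allclose(bh_qvalues(np.array([0.04, 1.0])), [0.08, 1.0])

    def test_oracle_equivalence_many_random(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_qvalues(p), oracles.bh_qvalues(p),
                               atol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=500)
        q = bh_qvalues(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)


class TestDCMSTrack:
    def test_end_to_end_shapes_and_determinism(self, rng):
        from dcmscan.dcms import DCMSConfig

        X = rng.normal(size=(300, 5))
        tails = ["right", "right", "right", "left", "left"]
        cfg = DCMSConfig(mcd_nsamp=200)
        t1 = dcms_track(X, tails, cfg, seed=11)
        t2 = dcms_track(X, tails, cfg, seed=11)
        assert np.array_equal(t1["dcms"], t2["dcms"])
        assert np.array_equal(t1["q"], t2["q"])
        assert t1["sigma"] > 0
        assert np.all(t1["q"] >= t1["p"] - 1e-15)
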