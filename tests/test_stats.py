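import numpy as np
import pytest

import oracles
from conftest import make_matrix, random_matrix
from dcmscan.io import MISSING
from dcmscan.stats import (WindowConfig, haplotype_homozygosity,
                           running_median, site_pi, smooth_by_chromosome,
                           tajimas_d, weir_cockerham_fst)


def two_pop_matrix(g1_freq, g2_freq, n1, n2, rng, n_loci=1):
    """Two subpopulations with given alt-allele frequencies."""
    a1 = (rng.random((2 * n1, n_loci)) < g1_freq).astype(np.int8)
    a2 = (rng.random((2 * n2, n_loci)) < g2_freq).astype(np.int8)
    labels = ["p1"] * n1 + ["p2"] * n2
    return make_matrix(np.vstack([a1, a2]), subpop=labels)


class TestWeirCockerhamFst:
    def test_fixed_difference_is_one(self):
        alleles = np.vstack([np.zeros((20, 1)), np.ones((20, 1))]).astype(np.int8)
        mat = make_matrix(alleles, subpop=["p1"] * 10 + ["p2"] * 10)
        assert weir_cockerham_fst(mat)[0] == pytest.approx(1.0)

    def test_identical_pops_clamped_to_zero(self):
        block = np.tile([0, 1, 0, 0, 1, 1, 0, 1], (1, 1)).T.astype(np.int8)
        alleles = np.vstack([block, block])
        mat = make_matrix(alleles, subpop=["p1"] * 4 + ["p2"] * 4)
        assert weir_cockerham_fst(mat)[0] == 0.0

    def test_against_direct_formula(self, rng):
        mat = two_pop_matrix(0.8, 0.2, 20, 20, rng)
        got = weir_cockerham_fst(mat)[0]
        g = mat.genotypes()
        want = oracles.wc_fst_value(g[:20, 0], g[20:, 0])
        assert got == pytest.approx(max(want, 0.0), abs=1e-12)

    def test_oracle_equivalence_random(self, rng):
        mat = two_pop_matrix(
            rng.uniform(0.1, 0.9, 120), rng.uniform(0.1, 0.9, 120),
            15, 25, rng, n_loci=120,
        )
        got = weir_cockerham_fst(mat)
        g = mat.genotypes()
        for j in range(mat.n_loci):
            want = oracles.wc_fst_value(g[:15, j], g[15:, j])
            if np.isnan(want):
                assert np.isnan(got[j])
            else:
                assert got[j] == pytest.approx(
                    min(max(want, 0.0), 1.0), abs=1e-12)

    def test_requires_two_subpopulations(self, rng):
        mat = random_matrix(rng)
        with pytest.raises(ValueError):
            weir_cockerham_fst(mat, ["p1"] * mat.n_samples)

    def test_bounded_zero_one(self, rng):
        mat = two_pop_matrix(
            rng.uniform(0, 1, 200), rng.uniform(0, 1, 200), 10, 10, rng,
            n_loci=200,
        )
        v = weir_cockerham_fst(mat)
        ok = ~np.isnan(v)
        assert np.all((v[ok] >= 0) & (v[ok] <= 1))


class TestHaplotypeHomozygosity:
    def test_single_class(self):
        alleles = np.tile([0, 1, 1, 0], (8, 1)).astype(np.int8)
        mat = make_matrix(alleles)
        h1, h12 = haplotype_homozygosity(mat, h_window=4, h_step=1)
        assert h1[2] == pytest.approx(1.0)  # window centre offset 4//2
        assert h12[2] == pytest.approx(1.0)

    def test_two_equal_classes(self):
        alleles = np.array([[0, 0, 0, 0], [1, 1, 1, 1]] * 4, dtype=np.int8)
        mat = make_matrix(alleles)
        h1, h12 = haplotype_homozygosity(mat, h_window=4)
        assert h1[2] == pytest.approx(0.5)
        assert h12[2] == pytest.approx(1.0)

    def test_four_equal_classes(self):
        alleles = np.array(
            [[0, 0, 0, 0], [1, 1, 1, 1], [0, 1, 0, 1], [1, 0, 1, 0]] * 2,
            dtype=np.int8,
        )
        mat = make_matrix(alleles)
        h1, h12 = haplotype_homozygosity(mat, h_window=4)
        assert h1[2] == pytest.approx(0.25)
        assert h12[2] == pytest.approx(0.375)

    def test_short_chromosome_all_missing(self, rng, caplog):
        mat = random_matrix(rng, n_samples=4, n_loci=5)
        h1, h12 = haplotype_homozygosity(mat, h_window=14)
        assert np.isnan(h1).all() and np.isnan(h12).all()

    def test_oracle_equivalence_and_ordering(self, rng):
        mat = random_matrix(rng, n_samples=6, n_loci=40)
        w = 5
        h1, h12 = haplotype_homozygosity(mat, h_window=w)
        for start in range(0, 40 - w + 1):
            centre = start + w // 2
            o1, o12 = oracles.h1_h12_values(mat.alleles[:, start:start + w])
            assert h1[centre] == pytest.approx(o1, abs=1e-12)
            assert h12[centre] == pytest.approx(o12, abs=1e-12)
            K = len({tuple(r) for r in mat.alleles[:, start:start + w]})
            assert 1.0 / K <= h1[centre] <= h12[centre] <= 1.0

    def test_missing_haplotypes_excluded(self):
        alleles = np.array(
            [[0, 0, 0, 0], [0, 0, 0, 0], [1, MISSING, 1, 1], [1, 1, 1, 1]],
            dtype=np.int8,
        )
        mat = make_matrix(alleles)
        h1, _ = haplotype_homozygosity(mat, h_window=4)
        # only 3 complete haplotypes: freqs (2/3, 1/3)
        assert h1[2] == pytest.approx((2 / 3) ** 2 + (1 / 3) ** 2)


class TestTajimasD:
    def test_empty_bin_is_zero(self):
        alleles = np.zeros((6, 4), dtype=np.int8)  # no segregating sites
        mat = make_matrix(alleles, pos=[10, 20, 30, 40])
        assert np.all(tajimas_d(mat, 1000) == 0.0)

    def test_four_haplotype_example(self):
        alleles = np.array(
            [[0, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 1], [0, 1, 1, 1]],
            dtype=np.int8,
        )
        mat = make_matrix(alleles, pos=[10, 20, 30, 40])
        want = oracles.tajimas_d_value(alleles)
        got = tajimas_d(mat, 1000)
        assert np.allclose(got, want, atol=1e-12)

    def test_oracle_equivalence_random_bins(self, rng):
        for _ in range(30):
            mat = random_matrix(rng, n_samples=5, n_loci=20,
                                maf_range=(0.0, 1.0))
            got = tajimas_d(mat, 10**9)  # single bin
            want = oracles.tajimas_d_value(mat.alleles)
            assert np.allclose(got, want, atol=1e-12)

    def test_bin_assignment(self, rng):
        mat = random_matrix(rng, n_samples=5, n_loci=10, spacing=100)
        d = tajimas_d(mat, 500)  # positions 100..1000 -> bins of 5 SNPs
        assert len(set(np.round(d[:5], 12))) == 1
        assert len(set(np.round(d[5:], 12))) == 1

    def test_too_few_haplotypes_is_an_error(self):
        mat = make_matrix([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            tajimas_d(mat)

    def test_calibrated_near_zero_on_neutral_spectrum(self, rng):
        """Site frequencies drawn from the neutral 1/i spectrum give
        Tajima's D centred near 0 (this is the regime the statistic is
        normalized for; ascertained or drifted data shift it)."""
        n, S, n_bins = 40, 25, 60
        weights = 1.0 / np.arange(1, n)
        weights /= weights.sum()
        ds = []
        for _ in range(n_bins):
            cols = []
            for _ in range(S):
                i = rng.choice(np.arange(1, n), p=weights)
                col = np.zeros(n, dtype=np.int8)
                col[rng.choice(n, size=i, replace=False)] = 1
                cols.append(col)
            mat = make_matrix(np.column_stack(cols))
            ds.append(tajimas_d(mat, 10**9)[0])
        assert abs(np.mean(ds)) < 0.5


class TestSitePi:
    @pytest.mark.parametrize(
        "j,n,expected",
        [(0, 8, 0.0), (8, 8, 0.0), (2, 4, 2 / 3), (3, 10, 7 / 15)],
    )
    def test_closed_form(self, j, n, expected):
        col = np.array([1] * j + [0] * (n - j), dtype=np.int8).reshape(n, 1)
        mat = make_matrix(col)
        assert site_pi(mat)[0] == pytest.approx(expected, abs=1e-12)
        assert site_pi(mat)[0] == pytest.approx(
            oracles.site_pi_value(col[:, 0]) if 0 < j < n else 0.0)

    def test_maximal_at_half(self, rng):
        n = 12
        vals = []
        for j in range(n + 1):
            col = np.array([1] * j + [0] * (n - j), dtype=np.int8).reshape(n, 1)
            mat = make_matrix(col)
            vals.append(site_pi(mat)[0])
        assert np.argmax(vals) == n // 2

    def test_oracle_equivalence_with_missing(self, rng):
        alleles = rng.integers(0, 2, size=(10, 50)).astype(np.int8)
        alleles[rng.random((10, 50)) < 0.2] = MISSING
        mat = make_matrix(alleles)
        got = site_pi(mat)
        for j in range(50):
            want = oracles.site_pi_value(alleles[:, j])
            if np.isnan(want):
                assert np.isnan(got[j])
            else:
                assert got[j] == pytest.approx(want, abs=1e-12)


class TestRunningMedian:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.3)
        assert np.array_equal(running_median(x, 31), x)

    def test_isolated_outlier_removed(self):
        x = np.zeros(40)
        x[17] = 1.0
        assert np.all(running_median(x, 31) == 0.0)

    def test_r_runmed_example(self):
        got = running_median(np.array([1.0, 9, 2, 8, 3]), 3)
        assert np.array_equal(got, [2, 2, 8, 3, 3])

    def test_matches_naive_with_missing(self, rng):
        x = rng.normal(size=200)
        x[rng.random(200) < 0.1] = np.nan
        got = running_median(x, 31)
        want = oracles.running_median_constant(x, 31)
        assert np.allclose(got, want)

    def test_monotone_transform_commutes(self, rng):
        """Median smoothing commutes with monotone transforms."""
        x = rng.normal(size=100)
        f = np.exp
        assert np.allclose(f(running_median(x, 9)),
                           running_median(f(x), 9))

    def test_smooth_by_chromosome_respects_boundaries(self, rng):
        mat = random_matrix(rng, n_samples=4, n_loci=20,
                            chrom=["1"] * 10 + ["2"] * 10)
        v = np.r_[np.zeros(10), np.ones(10)]
        out = smooth_by_chromosome(mat, v, 5)
        assert np.all(out[:10] == 0) and np.all(out[10:] == 1)


def test_window_config_validation():
    with pytest.raises(ValueError):
        WindowConfig(smooth_k=4)
    with pytest.raises(ValueError):
        WindowConfig(h_window=1)
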