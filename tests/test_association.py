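import numpy as np
import pytest
from scipy import stats

from braindyn import synthetic
from braindyn.association import (
    ancova_metric,
    fdr_bh,
    hemisphere_shuffle_test,
    map_association,
    partial_pearson,
    residual_normality,
    spearman_map_association,
    spin_permutations,
    spin_test,
)
from braindyn.nbs import DesignMatrix
from braindyn.validation import brute_bh, brute_partial_r, brute_spearman


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        assert spearman_map_association(x, 2 * x + 1) == pytest.approx(1.0)
        assert spearman_map_association(x, -x) == pytest.approx(-1.0)

    def test_tied_values_match_rank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 4.0, 7.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 6.0, 8.0, 7.0])
        assert spearman_map_association(x, y) == pytest.approx(
            brute_spearman(x, y), abs=1e-12
        )

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_map_association(np.ones(8), np.arange(8.0))


class TestSpin:
    def test_identical_maps_minimum_p(self, small_atlas):
        cort = small_atlas.cortical
        x = synthetic.generate_autocorrelated_map(small_atlas, 0.5, seed=1)[cort]
        res = spin_test(x, x.copy(), small_atlas, n_permutations=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_null_maps_are_permutations(self, small_atlas):
        perms = spin_permutations(small_atlas, 50, seed=1)
        n_c = int(small_atlas.cortical.sum())
        for p in perms:
            assert sorted(p) == list(range(n_c))
        # and hemisphere membership is preserved
        hemis = small_atlas.hemispheres[small_atlas.cortical]
        for p in perms:
            assert np.all(hemis[p] == hemis)

    def test_seed_reproducible(self, small_atlas):
        a = spin_permutations(small_atlas, 10, seed=5)
        b = spin_permutations(small_atlas, 10, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_missing_coordinates_rejected(self, small_atlas):
        small_atlas.coordinates[0, 0] = np.nan
        with pytest.raises(ValueError, match="coordinates"):
            spin_permutations(small_atlas, 5, seed=0)


class TestHemisphereShuffle:
    def test_constant_within_hemisphere_p_one(self, small_atlas):
        sub = ~small_atlas.cortical
        hemis = small_atlas.hemispheres[sub]
        x = np.where(hemis == "L", 1.0, 2.0)
        y = np.random.default_rng(0).standard_normal(hemis.size)
        res = hemisphere_shuffle_test(x, y, hemis, n_permutations=100, seed=1)
        assert res.p_value == 1.0

    def test_planted_monotone_association_detected(self):
        atlas = synthetic.make_synthetic_atlas(n_cortical=4, n_subcortical=20, seed=2)
        hemis = atlas.hemispheres[~atlas.cortical]
        rng = np.random.default_rng(3)
        x = np.arange(20.0)
        y = x + rng.normal(0, 2.0, 20)
        res = hemisphere_shuffle_test(x, y, hemis, n_permutations=999, seed=4)
        assert res.p_value < 0.05

    def test_same_seed_identical_p(self, small_atlas):
        sub = ~small_atlas.cortical
        hemis = small_atlas.hemispheres[sub]
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, hemis.size))
        a = hemisphere_shuffle_test(x, y, hemis, n_permutations=200, seed=9)
        b = hemisphere_shuffle_test(x, y, hemis, n_permutations=200, seed=9)
        assert a.p_value == b.p_value

    def test_single_region_hemisphere_warns(self):
        hemis = np.array(["L", "R", "R", "R", "R", "R"])
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="stays fixed"):
            hemisphere_shuffle_test(
                rng.standard_normal(6), rng.standard_normal(6), hemis,
                n_permutations=50, seed=0,
            )


class TestWholeBrainAssociation:
    def test_combined_null_is_whole_brain_permutation(self, small_atlas):
        rng = np.random.default_rng(1)
        x = synthetic.generate_autocorrelated_map(small_atlas, 0.5, seed=3)
        y = synthetic.generate_autocorrelated_map(small_atlas, 0.5, seed=4)
        res = map_association(x, y, small_atlas, n_permutations=100, seed=5)
        assert 0.0 < res.p_value <= 1.0
        assert res.scheme == "spin+shuffle"


class TestFdr:
    def test_worked_example(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.2, 0.2, 0.2]), 0.2)

    def test_matches_bruteforce_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        adj = fdr_bh(p)
        np.testing.assert_allclose(adj, brute_bh(p), atol=1e-12)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestAncovaMetric:
    def test_null_calibration(self):
        ps = []
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            n = 30
            group = np.array([0] * 15 + [1] * 15)
            cov = rng.standard_normal((n, 2))
            design = DesignMatrix(
                group=group, covariates=cov, covariate_names=("c1", "c2")
            )
            y = rng.standard_normal(n)
            _, p = ancova_metric(y, design)
            ps.append(p)
        assert stats.kstest(np.array(ps), "uniform").pvalue > 0.01

    def test_confound_only_signal_gives_null_group_effect(self):
        # y depends only on a covariate that also differs between groups:
        # after adjustment the group term carries no signal
        rng = np.random.default_rng(3)
        n = 60
        group = np.array([0] * 30 + [1] * 30)
        age = np.concatenate([rng.uniform(20, 35, 30), rng.uniform(35, 50, 30)])
        cov = np.column_stack([age, rng.standard_normal(n)])
        y = 0.5 * age + rng.normal(0, 0.1, n)
        design = DesignMatrix(group=group, covariates=cov, covariate_names=("age", "x"))
        f, p = ancova_metric(y, design)
        assert p > 0.05

    def test_matches_bruteforce_nested_f(self):
        rng = np.random.default_rng(4)
        n = 8
        design = DesignMatrix(
            group=np.array([0, 0, 0, 0, 1, 1, 1, 1]),
            covariates=rng.standard_normal((n, 2)),
            covariate_names=("a", "b"),
        )
        y = rng.standard_normal(n)
        f, _ = ancova_metric(y, design)
        from braindyn.validation import brute_nested_f

        assert f == pytest.approx(
            brute_nested_f(y, design.full(), design.reduced()), abs=1e-10
        )


class TestPartialPearson:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 30))
        r, p = partial_pearson(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_covariate_explained_part_only(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal(40)
        x = rng.standard_normal(40)
        y = x + 3.0 * z  # y = x plus covariate-explained part
        r, _ = partial_pearson(x, y, z[:, None])
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_matches_recursive_formula(self):
        rng = np.random.default_rng(7)
        x, y, z = rng.standard_normal((3, 10))
        r, _ = partial_pearson(x, y, z[:, None])
        assert r == pytest.approx(brute_partial_r(x, y, z), abs=1e-12)

    def test_sample_size_guard(self):
        with pytest.raises(ValueError, match="observations"):
            partial_pearson(np.arange(4.0), np.arange(4.0), np.ones((4, 2)))


class TestResidualNormality:
    def test_gaussian_residuals_mostly_pass(self):
        passes = 0
        for s in range(60):
            rng = np.random.default_rng(2000 + s)
            cov = rng.standard_normal((60, 2))
            x = cov @ [1.0, -0.5] + rng.standard_normal(60)
            _, p = residual_normality(x, cov)
            if p > 0.05:
                passes += 1
        assert passes >= 54  # >= 90%

    def test_exponential_residuals_mostly_rejected(self):
        rejects = 0
        for s in range(60):
            rng = np.random.default_rng(3000 + s)
            cov = rng.standard_normal((60, 2))
            x = cov @ [1.0, -0.5] + rng.exponential(1.0, 60)
            _, p = residual_normality(x, cov)
            if p < 0.05:
                rejects += 1
        assert rejects >= 54

    def test_perfect_fit_error(self):
        cov = np.arange(10.0)[:, None]
        x = 2.0 * cov[:, 0] + 1.0
        with pytest.raises(ValueError, match="constant residuals"):
            residual_normality(x, cov)
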