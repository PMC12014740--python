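import warnings

import numpy as np
import pytest

from braindyn import synthetic
from braindyn.synthetic import (
    CohortSpec,
    GeneratorError,
    RegimeSpec,
    build_regime_covariances,
    default_module_assignment,
    generate_autocorrelated_map,
    generate_cohort,
    generate_connectivity_cohort,
    regime_transition_matrix,
    sample_regime_sequence,
)


class TestRegimeCovariances:
    def test_segregated_block_structure(self):
        spec = RegimeSpec(
            n_regions=8,
            module_assignment=default_module_assignment(8, 2),
            within_corr_segregated=0.6,
            between_corr_segregated=0.0,
        )
        seg, _ = build_regime_covariances(spec)
        block = np.full((4, 4), 0.6)
        np.fill_diagonal(block, 1.0)
        np.testing.assert_allclose(seg[:4, :4], block)
        np.testing.assert_allclose(seg[4:, 4:], block)
        np.testing.assert_allclose(seg[:4, 4:], 0.0)

    def test_zero_global_corr_gives_identity(self):
        spec = RegimeSpec(
            n_regions=5,
            module_assignment=np.zeros(5, dtype=int),
            global_corr_integrated=0.0,
        )
        _, integ = build_regime_covariances(spec)
        np.testing.assert_allclose(integ, np.eye(5))

    def test_positive_definiteness_gate_matches_eigendecomposition(self):
        # accepted/rejected exactly when the smallest eigenvalue is positive
        spec = RegimeSpec(
            n_regions=100,
            module_assignment=default_module_assignment(100, 2),
            within_corr_segregated=0.99,
            between_corr_segregated=0.98,
        )
        same = spec.module_assignment[:, None] == spec.module_assignment[None, :]
        corr = np.where(same, 0.99, 0.98)
        np.fill_diagonal(corr, 1.0)
        min_eig = np.linalg.eigvalsh(corr)[0]
        if min_eig > 0:
            build_regime_covariances(spec)
        else:
            with pytest.raises(GeneratorError, match="eigenvalue"):
                build_regime_covariances(spec)

    def test_noise_sd_scales_covariance(self):
        spec = RegimeSpec(
            n_regions=4, module_assignment=np.zeros(4, dtype=int), noise_sd=2.0
        )
        seg, _ = build_regime_covariances(spec)
        assert seg[0, 0] == pytest.approx(4.0)


class TestRegimeSequence:
    def test_stationary_occupancy_exact(self):
        for occ in (0.3, 0.5, 0.64):
            t = regime_transition_matrix(0.9, occ)
            pi = np.array([1 - occ, occ])
            np.testing.assert_allclose(pi @ t, pi, atol=1e-12)

    def test_long_run_occupancy(self):
        seq = sample_regime_sequence(0.9, 0.5, 100_000, seed=1)
        assert abs(seq.mean() - 0.5) < 0.01

    def test_degenerate_occupancy_constant(self):
        with pytest.warns(UserWarning, match="degenerate"):
            seq = sample_regime_sequence(0.9, 1.0, 50, seed=0)
        assert np.all(seq == 1)

    def test_same_seed_reproducible(self):
        a = sample_regime_sequence(0.9, 0.64, 500, seed=7)
        b = sample_regime_sequence(0.9, 0.64, 500, seed=7)
        np.testing.assert_array_equal(a, b)


class TestCohort:
    def test_null_effect_identical_templates(self):
        regimes = synthetic.default_regimes(n_regions=10, n_modules=2)
        cohort = generate_cohort(CohortSpec(n_per_group=(2, 2), n_timepoints=40), regimes)
        for a, b in zip(cohort.regime_templates["control"], cohort.regime_templates["case"]):
            np.testing.assert_array_equal(a, b)

    def test_fixed_seed_bit_identical(self):
        regimes = synthetic.default_regimes(n_regions=10, n_modules=2)
        spec = CohortSpec(n_per_group=(2, 2), n_timepoints=40, seed=5)
        c1 = generate_cohort(spec, regimes)
        c2 = generate_cohort(spec, regimes)
        for s1, s2 in zip(c1.subjects, c2.subjects):
            np.testing.assert_array_equal(s1.series.values, s2.series.values)
            np.testing.assert_array_equal(s1.regime_sequence, s2.regime_sequence)
            assert s1.covariates == s2.covariates

    def test_effect_recovered_in_sample_correlation(self):
        # case-minus-control correlation on planted edges, within the
        # integrated regime, matches the planted offset (sample oracle)
        effect = 0.2
        edges = [(0, 5), (1, 6)]
        regimes = synthetic.default_regimes(n_regions=10, n_modules=2)
        spec = CohortSpec(
            n_per_group=(20, 20),
            n_timepoints=300,
            integrated_occupancy=0.64,
            effect_edges=edges,
            effect_size=effect,
            seed=3,
        )
        cohort = generate_cohort(spec, regimes)
        deltas = []
        for i, j in edges:
            by_group = {"control": [], "case": []}
            for sub in cohort.subjects:
                mask = sub.regime_sequence == 1
                x = sub.series.values[mask]
                by_group[sub.group].append(np.corrcoef(x[:, i], x[:, j])[0, 1])
            deltas.append(np.mean(by_group["case"]) - np.mean(by_group["control"]))
        assert abs(np.mean(deltas) - effect) < 0.05

    def test_effect_out_of_range_rejected(self):
        regimes = synthetic.default_regimes(n_regions=6, n_modules=2)
        spec = CohortSpec(
            n_per_group=(1, 1), n_timepoints=30,
            effect_edges=[(0, 1)], effect_size=0.9,
        )
        # within-module corr 0.6 + 0.9 > 1
        with pytest.raises(GeneratorError, match="outside"):
            generate_cohort(spec, regimes)

    def test_single_regime_covariance_convergence(self):
        # Frobenius distance to the template shrinks roughly as 1/sqrt(T)
        regimes = synthetic.default_regimes(n_regions=10, n_modules=2)
        seg, _ = build_regime_covariances(regimes)
        rng = np.random.default_rng(0)
        chol = np.linalg.cholesky(seg)
        dists = {}
        for t in (500, 5000):
            x = rng.standard_normal((t, 10)) @ chol.T
            emp = np.corrcoef(x, rowvar=False)
            dists[t] = np.linalg.norm(emp - seg / regimes.noise_sd**2)
        assert dists[5000] < dists[500]
        assert dists[5000] < 0.15


class TestAutocorrelatedMap:
    def test_same_seed_identical(self, small_atlas):
        a = generate_autocorrelated_map(small_atlas, 0.5, seed=4)
        b = generate_autocorrelated_map(small_atlas, 0.5, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_zero_length_scale_uncorrelated_neighbours(self, small_atlas):
        # Monte Carlo over 200 seeds: nearest-neighbour correlation ~ 0
        cort = np.nonzero(small_atlas.cortical)[0]
        coords = small_atlas.coordinates[cort]
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i = 0
        j = int(np.argmin(d[0]))
        vals = np.array(
            [
                generate_autocorrelated_map(small_atlas, 0.0, seed=s)[cort][[i, j]]
                for s in range(200)
            ]
        )
        r = np.corrcoef(vals[:, 0], vals[:, 1])[0, 1]
        assert abs(r) < 0.2

    def test_large_length_scale_near_constant(self, small_atlas):
        m = generate_autocorrelated_map(small_atlas, 1e6, seed=2)
        cort = small_atlas.cortical
        assert np.std(m[cort]) < 1e-2 * max(1.0, abs(np.mean(m[cort])))

    def test_missing_coordinates_error(self):
        atlas = synthetic.make_synthetic_atlas(n_cortical=4, n_subcortical=2, seed=0)
        atlas.coordinates[0] = np.nan
        with pytest.raises(GeneratorError, match="coordinates"):
            generate_autocorrelated_map(atlas, 0.5, seed=0)


class TestConnectivityCohort:
    def test_planted_standardized_effect(self):
        edges = [(0, 1), (2, 3)]
        mats, subj = generate_connectivity_cohort(
            6, (200, 200), effect_edges=edges, effect_d=1.0, subject_sd=0.1, seed=0
        )
        z = np.arctanh(np.clip(np.array(mats), -0.999999, 0.999999))
        g = subj.group_indicator().astype(bool)
        for i, j in edges:
            d = (z[g, i, j].mean() - z[~g, i, j].mean()) / 0.1
            assert abs(d - 1.0) < 0.15
        # non-planted edge: no effect
        d0 = (z[g, 0, 5].mean() - z[~g, 0, 5].mean()) / 0.1
        assert abs(d0) < 0.3

    def test_null_cohort_group_exchangeable(self):
        # permutation p of a group test on a null cohort is uniform
        from braindyn.association import ancova_metric
        from braindyn.nbs import DesignMatrix

        ps = []
        for s in range(120):
            mats, subj = generate_connectivity_cohort(5, (10, 10), seed=500 + s)
            try:
                design = DesignMatrix.from_subject_table(subj)
            except ValueError:
                continue  # e.g. an all-male draw makes sex collinear
            edge = np.array([m[0, 1] for m in mats])
            _, p = ancova_metric(edge, design)
            ps.append(p)
        from scipy import stats

        assert stats.kstest(np.array(ps), "uniform").pvalue > 0.01
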