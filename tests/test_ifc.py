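"""Seed time courses, correlation maps, Fisher z, group GLM, permutation test."""

import numpy as np
import pytest

import hippofc as h
from hippofc.meshes import make_grid_mesh


def make_series(values, tr=2.0):
    values = np.atleast_2d(np.asarray(values, float))
    return h.BoldSeries(values, np.arange(values.shape[0]), tr)


class TestSeedTimecourse:
    def test_identical_voxels_pass_through(self):
        s = make_series([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        tc = h.seed_timecourse(s, np.array([5, 5]), 5)
        assert np.allclose(tc, [1, 2, 3])

    def test_opposite_voxels_cancel(self):
        s = make_series([[1.0, -2.0, 3.0], [-1.0, 2.0, -3.0]])
        tc = h.seed_timecourse(s, np.array([1, 1]), 1)
        assert np.allclose(tc, 0)

    def test_arithmetic_mean(self):
        s = make_series([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        tc = h.seed_timecourse(s, np.array([1, 1]), 1)
        assert np.allclose(tc, [2, 2, 2])

    def test_empty_seed_names_the_seed(self):
        s = make_series([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="seed 9"):
            h.seed_timecourse(s, np.array([1]), 9)

    def test_parcellation_volume_lookup(self, small_truth, small_cohort):
        subj = small_cohort.subjects[0].hippocampus
        tc = h.seed_timecourse(subj, small_truth.true_parcel_labels, 1)
        labels = small_truth.true_parcel_labels.flat_labels(subj.location_ids)
        assert np.allclose(tc, subj.values[labels == 1].mean(axis=0))


class TestCorrelationMap:
    def test_identical_series_r_one(self, rng):
        seed = rng.standard_normal(50)
        out = h.correlation_map(seed, seed[None, :])
        assert np.isclose(out.values[0], 1.0)

    def test_negated_series_r_minus_one(self, rng):
        seed = rng.standard_normal(50)
        out = h.correlation_map(seed, -seed[None, :])
        assert np.isclose(out.values[0], -1.0)

    def test_hand_computed_pearson(self):
        out = h.correlation_map(np.array([1.0, 2, 3, 4]), np.array([[1.0, 2, 3, 5]]))
        assert np.isclose(out.values[0], 0.9827, atol=1e-4)

    def test_flat_vertex_gets_zero_and_flag(self, rng):
        seed = rng.standard_normal(20)
        out = h.correlation_map(seed, np.zeros((1, 20)))
        assert out.values[0] == 0.0 and out.flags[0]

    def test_zero_variance_seed_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            h.correlation_map(np.ones(10), np.random.default_rng(0).standard_normal((2, 10)))


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        z = h.fisher_z(h.VertexMap(np.array([0.0]), kind="r"))
        assert z.values[0] == 0.0

    def test_half_maps_to_atanh_half(self):
        z = h.fisher_z(h.VertexMap(np.array([0.5, -0.5]), kind="r"))
        assert np.isclose(z.values[0], 0.549306, atol=1e-6)
        assert np.isclose(z.values[0], -z.values[1])  # odd symmetry

    def test_unit_r_clamped_and_flagged(self):
        z = h.fisher_z(h.VertexMap(np.array([1.0]), kind="r"))
        assert np.isfinite(z.values[0]) and z.flags[0]
        assert np.isclose(z.values[0], np.arctanh(1 - 1e-7))


class TestGroupGLM:
    def test_one_sample_t_arithmetic(self):
        model = h.GroupModel(np.array([[0.4], [0.5], [0.6]]))
        t_map, p_map = h.group_glm(model)
        assert np.isclose(t_map.values[0], 8.6603, atol=1e-4)

    def test_symmetric_values_give_zero_t(self):
        model = h.GroupModel(np.array([[-1.0], [0.0], [1.0]]))
        t_map, _ = h.group_glm(model)
        assert np.isclose(t_map.values[0], 0.0)

    def test_orthogonal_covariate_leaves_intercept_unchanged(self, rng):
        # OLS orthogonality: a centred covariate orthogonal to the data
        # columns leaves the intercept estimate at the plain group mean
        z = rng.standard_normal((8, 3))
        zc = z - z.mean(axis=0)
        raw = rng.standard_normal(8)
        raw -= raw.mean()
        cov = raw - zc @ np.linalg.lstsq(zc, raw, rcond=None)[0]  # exact orthogonality
        assert np.abs(cov @ zc).max() < 1e-10
        model = h.GroupModel(z, covariates=cov[:, None])
        x = model.design_matrix()
        beta0 = np.linalg.lstsq(x, z, rcond=None)[0][0]
        assert np.allclose(beta0, z.mean(axis=0))
        # and the t statistic only changes through the df/variance estimate
        t_with, _ = h.group_glm(model)
        t_plain, _ = h.group_glm(h.GroupModel(z))
        assert np.sign(t_with.values).tolist() == np.sign(t_plain.values).tolist()

    def test_matches_statsmodels_per_vertex(self, rng):
        import statsmodels.api as sm

        z = rng.standard_normal((10, 4))
        cov = rng.standard_normal((10, 2))
        t_map, p_map = h.group_glm(h.GroupModel(z, covariates=cov))
        x = sm.add_constant(cov - cov.mean(axis=0))
        for v in range(4):
            fit = sm.OLS(z[:, v], x).fit()
            assert np.isclose(t_map.values[v], fit.tvalues[0], atol=1e-10)
            assert np.isclose(p_map.values[v], fit.pvalues[0], atol=1e-10)

    def test_collinear_covariates_rejected(self, rng):
        z = rng.standard_normal((6, 3))
        cov = np.column_stack([np.arange(6.0), 2.0 * np.arange(6.0)])
        with pytest.raises(ValueError, match="collinear|rank"):
            h.group_glm(h.GroupModel(z, covariates=cov))


class TestPermutationCorrect:
    def test_all_zero_maps_nothing_significant(self, grid_mesh):
        model = h.GroupModel(np.zeros((8, grid_mesh.n_vertices)))
        res = h.permutation_correct(model, grid_mesh, n_perm=200, rng_seed=0)
        assert not res.significance.values.any()

    def test_planted_patch_detected(self, grid_mesh, rng):
        # contiguous patch with subject-mean z = 1.0, sd 0.3 noise elsewhere
        v = grid_mesh.n_vertices
        patch = np.arange(100, 140)
        detected = 0
        runs = 10
        for i in range(runs):
            maps = 0.3 * rng.standard_normal((12, v))
            maps[:, patch] += 1.0
            res = h.permutation_correct(h.GroupModel(maps), grid_mesh,
                                        n_perm=300, rng_seed=i)
            frac = res.significance.values[patch].mean()
            detected += frac >= 0.9
        assert detected >= 9

    def test_sign_equivariance(self, grid_mesh, rng):
        maps = 0.5 * rng.standard_normal((10, grid_mesh.n_vertices))
        maps[:, :50] += 0.8
        a = h.permutation_correct(h.GroupModel(maps), grid_mesh, n_perm=300, rng_seed=3)
        b = h.permutation_correct(h.GroupModel(-maps), grid_mesh, n_perm=300, rng_seed=3)
        assert np.allclose(a.t_map.values, -b.t_map.values)
        assert np.array_equal(a.significance.values, b.significance.values)
        assert np.allclose(a.corrected_z.values, -b.corrected_z.values)

    def test_deterministic_given_seed(self, grid_mesh, rng):
        maps = rng.standard_normal((10, grid_mesh.n_vertices))
        a = h.permutation_correct(h.GroupModel(maps), grid_mesh, n_perm=200, rng_seed=5)
        b = h.permutation_correct(h.GroupModel(maps), grid_mesh, n_perm=200, rng_seed=5)
        assert np.array_equal(a.significance.values, b.significance.values)
        assert np.array_equal(a.max_null_sizes, b.max_null_sizes)

    def test_low_resolution_alpha_warns(self, grid_mesh, rng):
        maps = rng.standard_normal((8, grid_mesh.n_vertices))
        with pytest.warns(UserWarning, match="resolves"):
            h.permutation_correct(h.GroupModel(maps), grid_mesh, n_perm=100,
                                  cluster_alpha=0.01, rng_seed=0)

    def test_effect_growth_never_shrinks_detection(self, grid_mesh, rng):
        # monotonicity in expectation over seeded replicates
        patch = np.arange(200, 240)
        counts = []
        for effect in (0.6, 1.2):
            total = 0
            for i in range(5):
                local = np.random.default_rng(100 + i)
                maps = 0.4 * local.standard_normal((10, grid_mesh.n_vertices))
                maps[:, patch] += effect
                res = h.permutation_correct(h.GroupModel(maps), grid_mesh,
                                            n_perm=300, rng_seed=i)
                total += int(res.significance.values.sum())
            counts.append(total)
        assert counts[1] >= counts[0]
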