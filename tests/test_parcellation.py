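"""Group ICA, probability maps, k-means, validity index, elbow, QC, overlap."""

import itertools

import numpy as np
import pytest

import hippofc as h
from hippofc.synthetic import band_limited_signal


def brute_force_two_means(points: np.ndarray) -> float:
    """Optimal within-cluster SS over all 2-partitions (oracle for small V)."""
    v = len(points)
    best = np.inf
    for assign in itertools.product((0, 1), repeat=v - 1):
        labels = np.array((0,) + assign)
        if labels.max() == 0:
            continue
        ss = 0.0
        for c in (0, 1):
            grp = points[labels == c]
            if len(grp):
                ss += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, ss)
    return best


def within_ss(points: np.ndarray, labels: np.ndarray) -> float:
    return sum(
        ((points[labels == c] - points[labels == c].mean(axis=0)) ** 2).sum()
        for c in np.unique(labels)
    )


class TestGroupICA:
    def test_recovers_two_nonoverlapping_sources(self, rng):
        # two disjoint spatial sources with independent in-band time courses
        v, t = 80, 400
        s1 = np.zeros(v); s1[:20] = 1.0
        s2 = np.zeros(v); s2[50:] = 1.0
        tc1 = band_limited_signal(t, 2.0, 0.01, 0.1, rng)
        tc2 = band_limited_signal(t, 2.0, 0.01, 0.1, rng)
        data = np.outer(s1, tc1) + np.outer(s2, tc2) + 0.01 * rng.standard_normal((v, t))
        comps = h.group_ica(data, k=2, rng_seed=0)
        corr = np.abs(np.corrcoef(np.vstack([comps.spatial_maps, [s1, s2]]))[:2, 2:])
        # after matching by maximal |correlation| both sources are recovered
        assert max(corr[0, 0], corr[1, 0]) > 0.95
        assert max(corr[0, 1], corr[1, 1]) > 0.95
        assert corr.max(axis=1).min() > 0.95

    def test_single_broadcast_latent(self, rng):
        latent = band_limited_signal(300, 2.0, 0.01, 0.1, rng)
        data = np.tile(latent, (40, 1)) + 1e-4 * rng.standard_normal((40, 300))
        comps = h.group_ica(data, k=1, rng_seed=0)
        r = np.corrcoef(comps.time_courses[0], latent)[0, 1]
        assert abs(r) > 0.99

    def test_deterministic_given_seed(self, rng):
        data = rng.standard_normal((60, 100))
        a = h.group_ica(data, k=4, rng_seed=11)
        b = h.group_ica(data, k=4, rng_seed=11)
        assert np.array_equal(a.spatial_maps, b.spatial_maps)

    def test_maps_standardised_with_nonnegative_skewness(self, rng):
        data = rng.standard_normal((60, 100))
        comps = h.group_ica(data, k=3, rng_seed=0)
        assert np.allclose(comps.spatial_maps.mean(axis=1), 0, atol=1e-8)
        assert np.allclose(comps.spatial_maps.std(axis=1), 1, atol=1e-8)
        from scipy.stats import skew
        assert (skew(comps.spatial_maps, axis=1) >= -1e-12).all()

    def test_rank_deficient_data_reduces_k(self, rng):
        base = rng.standard_normal((3, 200))
        data = rng.standard_normal((30, 3)) @ base  # rank 3
        with pytest.warns(UserWarning, match="rank"):
            comps = h.group_ica(data, k=10, rng_seed=0)
        assert comps.k <= 3


class TestProbabilityFromMap:
    def test_constant_map_falls_back_to_equal_probabilities(self):
        p, fallback = h.probability_from_map(np.full(50, 2.0))
        assert fallback
        assert np.allclose(p, p[0])

    def test_bimodal_map_matches_bayes_posterior(self, rng):
        # null N(0,1) mass 0.8, active N(4,1) mass 0.2
        n = 10_000
        comp = rng.random(n) < 0.2
        x = np.where(comp, rng.normal(4.0, 1.0, n), rng.normal(0.0, 1.0, n))
        x[:2] = [4.0, 0.0]  # probe exactly the example values
        p, fallback = h.probability_from_map(x)
        assert not fallback
        assert p[0] > 0.95  # value 4 -> active
        assert p[1] < 0.05  # value 0 -> null

    def test_output_bounded_in_unit_interval(self, rng):
        p, _ = h.probability_from_map(rng.standard_normal(500))
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_monotone_above_null_mean(self, rng):
        n = 5000
        comp = rng.random(n) < 0.3
        x = np.sort(np.where(comp, rng.normal(3.0, 1.0, n), rng.normal(0.0, 1.0, n)))
        p, fallback = h.probability_from_map(x)
        assert not fallback
        above = x > 0.0
        assert (np.diff(p[above]) >= -1e-12).all()


class TestKMeans:
    def test_two_well_separated_pairs(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = h.kmeans_cluster(pts, 2, rng_seed=0)
        assert labels[0] == labels[1] != labels[2] == labels[3]

    def test_k_equals_one_total_ss(self, rng):
        pts = rng.standard_normal((20, 3))
        labels = h.kmeans_cluster(pts, 1, rng_seed=0)
        assert len(np.unique(labels)) == 1
        assert np.isclose(within_ss(pts, labels), ((pts - pts.mean(axis=0)) ** 2).sum())

    def test_k_equals_v_zero_ss(self, rng):
        pts = rng.standard_normal((6, 2))
        labels = h.kmeans_cluster(pts, 6, rng_seed=0)
        assert len(np.unique(labels)) == 6
        assert within_ss(pts, labels) < 1e-20

    def test_k_larger_than_v_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            h.kmeans_cluster(np.zeros((3, 1)), 4)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_optimum_small_instances(self, trial):
        rng = np.random.default_rng(trial)
        v = int(rng.integers(4, 13))
        dim = int(rng.integers(1, 4))
        pts = rng.standard_normal((v, dim))
        labels = h.kmeans_cluster(pts, 2, rng_seed=trial, n_init=20)
        assert np.isclose(within_ss(pts, labels), brute_force_two_means(pts), atol=1e-8)


class TestClusterValidityIndex:
    def test_hand_computed_example(self):
        pts = np.array([[0.0], [0.2], [10.0], [10.2]])
        labels = np.array([0, 0, 1, 1])
        # within mean distance 0.1, centroid distance 10.0
        assert np.isclose(h.cluster_validity_index(pts, labels), 0.01)

    def test_zero_when_points_sit_on_centroids(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0]])
        labels = np.array([0, 0, 1, 1])
        assert h.cluster_validity_index(pts, labels) == 0.0

    def test_invariant_to_duplicating_points(self, rng):
        pts = rng.standard_normal((12, 2)) + np.repeat([[0, 0], [8, 8]], 6, axis=0)
        labels = np.repeat([0, 1], 6)
        a = h.cluster_validity_index(pts, labels)
        b = h.cluster_validity_index(np.vstack([pts, pts]), np.hstack([labels, labels]))
        assert np.isclose(a, b)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            h.cluster_validity_index(np.zeros((4, 1)), np.zeros(4, int))


class TestSelectClusterNumber:
    def test_knee_of_hand_curve(self, monkeypatch):
        # bypass k-means: inject the exact CVI curve from known labelings
        from hippofc import parcellation as p

        curve = {2: 1.0, 3: 0.2, 4: 0.15, 5: 0.12}
        monkeypatch.setattr(p, "kmeans_cluster", lambda f, k, **kw: np.arange(len(f)) % k)
        monkeypatch.setattr(p, "cluster_validity_index", lambda f, lab: curve[len(np.unique(lab))])
        out = p.select_cluster_number(np.zeros((40, 2)), 2, 5)
        assert out.selected_k == 3

    def test_linear_curve_ties_to_k_min(self, monkeypatch):
        from hippofc import parcellation as p

        monkeypatch.setattr(p, "kmeans_cluster", lambda f, k, **kw: np.arange(len(f)) % k)
        monkeypatch.setattr(p, "cluster_validity_index", lambda f, lab: 1.0 - 0.1 * len(np.unique(lab)))
        with pytest.warns(UserWarning, match="knee"):
            out = p.select_cluster_number(np.zeros((40, 2)), 2, 6)
        assert out.selected_k == 2

    def test_invalid_scan_range_rejected(self):
        with pytest.raises(ValueError, match="k_min"):
            h.select_cluster_number(np.zeros((10, 2)), 5, 5)


class TestQCScreen:
    def test_in_band_latent_passes(self):
        tc = band_limited_signal(360, 2.0, 0.01, 0.1, 0)
        passes, report = h.qc_screen(tc[None, :], tr_seconds=2.0)
        assert passes[0]
        assert report["high_frequency_power_fraction"][0] < 0.25

    def test_high_frequency_sinusoid_fails(self):
        t = np.arange(360) * 2.0
        tc = np.sin(2 * np.pi * 0.2 * t)
        passes, report = h.qc_screen(tc[None, :], tr_seconds=2.0)
        assert not passes[0]
        assert report["high_frequency_power_fraction"][0] > 0.99

    def test_without_mask_only_spectral_criterion_applies(self):
        tc = band_limited_signal(360, 2.0, 0.01, 0.1, 1)
        passes, report = h.qc_screen(tc[None, :], tr_seconds=2.0)
        assert report["exclusion_correlation"] is None and passes[0]

    def test_exclusion_mask_correlation_fails_component(self, rng):
        tc = np.vstack([band_limited_signal(360, 2.0, 0.01, 0.1, i) for i in (2, 3)])
        mask = rng.standard_normal(100)
        fc_maps = np.vstack([mask + 0.1 * rng.standard_normal(100),
                             rng.standard_normal(100)])
        passes, report = h.qc_screen(tc, 2.0, fc_maps=fc_maps, exclusion_mask=mask)
        assert not passes[0] and passes[1]


class TestOverlapTable:
    def test_identical_parcellations_give_diagonal_100(self, small_truth):
        parc = small_truth.true_parcel_labels
        table = h.overlap_table(parc, parc)
        assert np.allclose(table, 100.0 * np.eye(parc.n_parcels))

    def test_even_split_column(self):
        a = np.zeros((4, 1, 1), dtype=np.int32)
        b = np.zeros((4, 1, 1), dtype=np.int32)
        a[:2] = 1; a[2:] = 2
        b[:] = 1
        table = h.overlap_table(h.ParcellationVolume(a), h.ParcellationVolume(b))
        assert np.allclose(table[:, 0], [50.0, 50.0])

    def test_planted_fraction_recovered(self):
        # one functional parcel covering 56% of one anatomical label
        n = 100
        a = np.zeros((n, 1, 1), dtype=np.int32)  # anatomical: one label
        b = np.zeros((n, 1, 1), dtype=np.int32)
        a[:] = 1
        b[:56] = 1; b[56:] = 2
        table = h.overlap_table(h.ParcellationVolume(b), h.ParcellationVolume(a))
        assert np.isclose(table[0, 0], 56.0)

    def test_columns_sum_to_100_when_covered(self, small_truth):
        table = h.overlap_table(small_truth.anatomical_labels,
                                small_truth.true_parcel_labels)
        assert np.allclose(table.sum(axis=0), 100.0)

    def test_mask_mismatch_rejected(self, small_truth):
        other = np.zeros_like(small_truth.true_parcel_labels.labels)
        other[0, 0, 0] = 1
        with pytest.raises(ValueError, match="mask"):
            h.overlap_table(small_truth.true_parcel_labels, h.ParcellationVolume(other))


class TestEndToEndRecovery:
    def test_adjusted_rand_index_with_correct_k(self, small_spec, small_truth, small_cohort):
        from sklearn.metrics import adjusted_rand_score

        hip = [s.hippocampus for s in small_cohort.subjects]
        res = h.parcellate(hip, small_truth.true_parcel_labels.labels.shape,
                           ica_k=8, fixed_k=6, rng_seed=0)
        ids = hip[0].location_ids
        ari = adjusted_rand_score(
            small_truth.true_parcel_labels.labels.ravel()[ids],
            res.parcellation.labels.ravel()[ids],
        )
        assert ari >= 0.8

    def test_recovered_labels_partition_and_order(self, small_spec, small_truth, small_cohort):
        hip = [s.hippocampus for s in small_cohort.subjects]
        res = h.parcellate(hip, small_truth.true_parcel_labels.labels.shape,
                           ica_k=8, fixed_k=6, rng_seed=0)
        parc = res.parcellation
        assert parc.same_mask(small_truth.true_parcel_labels)
        cents = [np.argwhere(parc.labels == pid)[:, 0].mean() for pid in parc.parcel_ids]
        assert np.all(np.diff(cents) >= 0)
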