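"""Parcellation: heterogeneity oracle, Ward recovery, RGS behavior."""

import numpy as np
import pytest
from scipy.ndimage import label as cc_label
from sklearn.metrics import adjusted_rand_score

from fcgraph.cohort import SubjectVolume
from fcgraph.errors import DegenerateInputError, EmptyParcellationError
from fcgraph.parcellation import (
    Cluster,
    Parcellation,
    Region,
    atlas_parcellate,
    broken_stick,
    extract_mean_timeseries,
    heterogeneity,
    parcellation_summary,
    rgs_grow,
    rgs_select,
    ward_parcellate,
)


def _subject_from_array(data):
    return SubjectVolume(
        data=data,
        mask=np.ones(data.shape[:3], dtype=bool),
        tr_seconds=3.0,
        subject_id="t",
        condition="C",
    )


class TestHeterogeneity:
    def test_broken_stick_sums_to_n(self):
        # sum_n sum_{i=n}^{N} 1/i telescopes to N
        for n in (2, 5, 20):
            assert np.isclose(broken_stick(n).sum(), n)

    def test_single_signal_gives_n0_one(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 4 * np.pi, 100)
        base = np.sin(t)
        series = np.tile(base, (20, 1)) + 1e-3 * rng.standard_normal((20, 100))
        res = heterogeneity(series)
        assert res.n0 == 1
        assert 1.0 <= res.h_interp < 2.0

    def test_two_orthogonal_signals_give_n0_two(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 4 * np.pi, 100)
        a, b = np.sin(t), np.cos(t)
        series = np.vstack([np.tile(a, (10, 1)), np.tile(b, (10, 1))])
        series = series + 1e-3 * rng.standard_normal(series.shape)
        assert heterogeneity(series).n0 == 2

    def test_three_signals_recovered(self):
        rng = np.random.default_rng(2)
        t = np.arange(120)
        sigs = [np.sin(2 * np.pi * f * t / 120) for f in (1, 3, 5)]
        series = np.vstack([np.tile(s, (7, 1)) for s in sigs])
        series = series + 1e-3 * rng.standard_normal(series.shape)
        assert heterogeneity(series).n0 == 3

    def test_constant_series_rejected(self):
        series = np.vstack([np.ones(50), np.random.default_rng(0).random(50)])
        with pytest.raises(DegenerateInputError):
            heterogeneity(series)

    def test_n0_invariant_to_permutation_and_scale(self):
        rng = np.random.default_rng(3)
        series = rng.standard_normal((12, 80))
        series[:6] += 3 * np.sin(np.linspace(0, 7, 80))
        ref = heterogeneity(series).n0
        perm = rng.permutation(12)
        assert heterogeneity(series[perm]).n0 == ref
        assert heterogeneity(5.0 * series).n0 == ref

    def test_eigenvalues_descending_and_scaled(self):
        rng = np.random.default_rng(4)
        series = rng.standard_normal((8, 60))
        res = heterogeneity(series)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.isclose(res.eigenvalues.sum(), 8)


class TestWard:
    def test_two_blocks_recovered_exactly(self, two_block_subject):
        parc = ward_parcellate(two_block_subject, k=2, p=1)
        gt = two_block_subject.ground_truth.labels[two_block_subject.mask]
        found = parc.assignment[two_block_subject.mask]
        assert adjusted_rand_score(gt, found) == 1.0

    def test_k1_returns_whole_mask(self, subject):
        parc = ward_parcellate(subject, k=1, p=1)
        assert parc.n_clusters == 1
        assert parc.clusters[0].size == subject.mask.sum()

    def test_min_size_filter(self, subject):
        parc = ward_parcellate(subject, k=8, p=10)
        assert all(c.size >= 10 for c in parc.clusters)
        assert [c.cluster_id for c in parc.clusters] == list(
            range(1, parc.n_clusters + 1)
        )

    def test_all_filtered_raises(self, subject):
        n_vox = int(subject.mask.sum())
        with pytest.raises(EmptyParcellationError):
            ward_parcellate(subject, k=8, p=n_vox)

    def test_k_exceeding_voxels_raises(self, subject):
        with pytest.raises(ValueError):
            ward_parcellate(subject, k=int(subject.mask.sum()) + 1, p=1)

    def test_clusters_spatially_connected(self, subject):
        parc = ward_parcellate(subject, k=6, p=1)
        for cluster in parc.clusters:
            vol = np.zeros(subject.mask.shape, dtype=bool)
            vol[tuple(cluster.voxels.T)] = True
            _, n_comp = cc_label(vol)
            assert n_comp == 1


class TestAtlasParcellate:
    def test_labels_inside_mask_become_clusters(self, subject):
        parc = atlas_parcellate(subject, subject.ground_truth)
        assert parc.n_clusters == subject.ground_truth.n_regions
        sizes = {c.size for c in parc.clusters}
        label_sizes = {
            int((subject.ground_truth.labels == r).sum())
            for r in range(1, subject.ground_truth.n_regions + 1)
        }
        assert sizes == label_sizes

    def test_region_outside_mask_dropped(self, subject):
        labels = subject.ground_truth
        masked = subject.mask.copy()
        masked[labels.labels == 1] = False
        trimmed = SubjectVolume(
            data=subject.data,
            mask=masked,
            tr_seconds=3.0,
            subject_id="t",
            condition="C",
        )
        parc = atlas_parcellate(trimmed, labels)
        assert parc.n_clusters == labels.n_regions - 1

    def test_shape_mismatch_rejected(self, subject, two_block_subject):
        with pytest.raises(ValueError):
            atlas_parcellate(subject, two_block_subject.ground_truth)

    def test_same_labels_give_same_node_count_across_subjects(self, small_config):
        from fcgraph.cohort import simulate_subject

        labels = simulate_subject(small_config, "C", 0).ground_truth
        counts = {
            atlas_parcellate(
                simulate_subject(small_config, cond, seed), labels
            ).n_clusters
            for cond, seed in (("C", 1), ("MCI", 2), ("AD", 3))
        }
        assert len(counts) == 1


class TestRGS:
    def test_homogeneous_field_grows_to_full_mask(self):
        rng = np.random.default_rng(0)
        base = np.sin(np.linspace(0, 6 * np.pi, 80))
        data = np.tile(base, (4, 4, 2, 1)) + 1e-3 * rng.standard_normal((4, 4, 2, 80))
        subj = _subject_from_array(data)
        regions = rgs_grow(subj, T=0.75)
        n_vox = 32
        assert min(r.size for r in regions) >= 0.95 * n_vox

    def test_no_region_spans_uncorrelated_blocks(self, two_block_subject):
        regions = rgs_grow(two_block_subject, T=0.75)
        labels = two_block_subject.ground_truth.labels
        for region in regions:
            voxel_labels = {labels[tuple(v)] for v in region.voxels}
            assert len(voxel_labels) == 1

    def test_extreme_threshold_keeps_regions_near_singleton(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((3, 3, 2, 60))
        subj = _subject_from_array(data)
        regions = rgs_grow(subj, T=0.999)
        assert max(r.size for r in regions) <= 2

    def test_grown_regions_are_connected(self, two_block_subject):
        regions = rgs_grow(two_block_subject, T=0.75)
        for region in regions:
            vol = np.zeros(two_block_subject.mask.shape, dtype=bool)
            vol[tuple(region.voxels.T)] = True
            _, n_comp = cc_label(vol)
            assert n_comp == 1


class TestRGSSelect:
    def test_disjoint_regions_both_selected(self):
        a = Region(center=(0, 0, 0), voxels=np.array([[0, 0, 0], [1, 0, 0]]))
        b = Region(center=(5, 0, 0), voxels=np.array([[5, 0, 0], [6, 0, 0]]))
        parc = rgs_select([a, b], p=1)
        assert parc.n_clusters == 2

    def test_dominant_region_absorbs_contained_centers(self):
        big = Region(
            center=(0, 0, 0), voxels=np.array([[i, 0, 0] for i in range(5)])
        )
        small = Region(center=(2, 0, 0), voxels=np.array([[2, 0, 0], [3, 0, 0]]))
        parc = rgs_select([big, small], p=1)
        assert parc.n_clusters == 1
        assert parc.clusters[0].size == 5

    def test_size_filter(self):
        a = Region(
            center=(0, 0, 0), voxels=np.array([[i, 0, 0] for i in range(60)])
        )
        b = Region(
            center=(0, 5, 0), voxels=np.array([[i, 5, 0] for i in range(40)])
        )
        parc = rgs_select([a, b], p=50)
        assert parc.n_clusters == 1

    def test_nothing_survives_raises(self):
        a = Region(center=(0, 0, 0), voxels=np.array([[0, 0, 0]]))
        with pytest.raises(EmptyParcellationError):
            rgs_select([a], p=5)

    def test_selected_centers_never_inside_other_clusters(self, two_block_subject):
        regions = rgs_grow(two_block_subject, T=0.75)
        parc = rgs_select(regions, p=1)
        for c1 in parc.clusters:
            for c2 in parc.clusters:
                if c1.cluster_id == c2.cluster_id:
                    continue
                assert not any(
                    tuple(v) == c1.center for v in c2.voxels
                ), "centre lies inside another selected cluster"


class TestMeanTimeSeriesAndSummary:
    def test_identical_voxels_mean_is_the_signal(self, subject):
        parc = atlas_parcellate(subject, subject.ground_truth)
        ts = extract_mean_timeseries(subject, parc)
        cluster = parc.clusters[0]
        manual = subject.data[tuple(cluster.voxels.T)].mean(axis=0)
        assert np.allclose(ts.series[0], manual)

    def test_two_voxel_average(self):
        data = np.zeros((2, 1, 1, 5))
        data[1, 0, 0] = 2.0
        subj = _subject_from_array(data)
        parc = Parcellation(
            assignment=np.ones((2, 1, 1), dtype=np.int32),
            clusters=[
                Cluster(
                    cluster_id=1,
                    voxels=np.array([[0, 0, 0], [1, 0, 0]]),
                    center=(0, 0, 0),
                )
            ],
            method_tag="manual",
        )
        ts = extract_mean_timeseries(subj, parc)
        assert np.allclose(ts.series[0], 1.0)

    def test_overlapping_clusters_share_voxels(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((3, 1, 1, 5))
        subj = _subject_from_array(data)
        shared = np.array([[1, 0, 0]])
        parc = Parcellation(
            assignment=np.zeros((3, 1, 1), dtype=np.int32),
            clusters=[
                Cluster(1, np.vstack([[0, 0, 0], shared]), (0, 0, 0)),
                Cluster(2, np.vstack([shared, [2, 0, 0]]), (2, 0, 0)),
            ],
            method_tag="manual",
        )
        ts = extract_mean_timeseries(subj, parc)
        assert np.allclose(ts.series[0], data[[0, 1], 0, 0].mean(axis=0))
        assert np.allclose(ts.series[1], data[[1, 2], 0, 0].mean(axis=0))

    def test_summary_mean_cluster_size(self, subject):
        sizes = (10, 20, 30)
        coords = np.argwhere(subject.mask)
        clusters = []
        start = 0
        for i, size in enumerate(sizes, start=1):
            clusters.append(
                Cluster(i, coords[start : start + size], tuple(coords[start]))
            )
            start += size
        parc = Parcellation(
            assignment=np.zeros(subject.mask.shape, dtype=np.int32),
            clusters=clusters,
            method_tag="manual",
        )
        stats = parcellation_summary(parc, subject)
        assert stats.n_nodes == 3
        assert stats.mean_voxels_per_node == 20

    def test_homogeneous_field_heterogeneity_near_one(self):
        rng = np.random.default_rng(5)
        base = np.sin(np.linspace(0, 6 * np.pi, 80))
        data = np.tile(base, (4, 4, 2, 1)) + 1e-3 * rng.standard_normal((4, 4, 2, 80))
        subj = _subject_from_array(data)
        parc = ward_parcellate(subj, k=1, p=1)
        stats = parcellation_summary(parc, subj)
        assert stats.n_nodes == 1
        assert 1.0 <= stats.mean_heterogeneity <= 2.0
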