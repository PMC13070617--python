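"""Tests of the CAP engine: frame selection, PCA, clustering, maps, matching."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from capdyn import (
    CleanRun,
    build_cap_maps,
    cluster_caps,
    consensus_cluster,
    extract_seed_timecourse,
    match_frames_to_caps,
    network_overlap,
    pca_reduce,
    select_active_frames,
    labels_to_volume_series,
)
from capdyn.caps import UNASSIGNED, pac_from_consensus


def _clean(signal, fd=None, seed=(0,)):
    return CleanRun(
        signal=np.asarray(signal, dtype=float),
        fd=np.zeros(signal.shape[0]) if fd is None else np.asarray(fd, float),
        tr_seconds=1.3,
        seed_voxels=np.asarray(seed),
    )


class TestSeedTimecourse:
    def test_single_voxel_seed_is_zscored_copy(self, rng):
        y = rng.standard_normal((30, 5))
        z = extract_seed_timecourse(_clean(y, seed=(2,)))
        expected = (y[:, 2] - y[:, 2].mean()) / y[:, 2].std()
        assert np.allclose(z, expected)

    def test_zscore_contract(self, rng):
        z = extract_seed_timecourse(_clean(rng.standard_normal((50, 8)), seed=(0, 3, 5)))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_empty_and_out_of_mask_seed_rejected(self, rng):
        y = rng.standard_normal((20, 4))
        with pytest.raises(ValueError):
            extract_seed_timecourse(_clean(y, seed=()))
        with pytest.raises(ValueError):
            extract_seed_timecourse(_clean(y, seed=(9,)))

    def test_zero_variance_seed_rejected(self):
        with pytest.raises(ValueError):
            extract_seed_timecourse(_clean(np.ones((20, 3))))


class TestFrameSelection:
    def test_strict_threshold(self):
        seed_z = np.array([1.0, 0.2, 0.9, 0.84, 2.0])
        sel = select_active_frames(seed_z, np.zeros(5))
        assert sel.retained_indices.tolist() == [0, 2, 4]  # 0.84 excluded

    def test_neighbour_scrubbing(self):
        seed_z = np.array([1.0, 0.2, 0.9, 0.84, 2.0])
        fd = np.array([0.0, 0.0, 0.6, 0.0, 0.0])
        sel = select_active_frames(seed_z, fd)
        assert sel.scrub_mask.tolist() == [False, True, True, True, False]
        assert sel.retained_indices.tolist() == [0, 4]

    def test_gaussian_tail_fraction(self, rng):
        z = rng.standard_normal(30_000)
        sel = select_active_frames(z, np.zeros(30_000))
        expected = 1.0 - norm.cdf(0.84)
        assert sel.n_retained / 30_000 == pytest.approx(expected, abs=0.01)

    def test_degenerate_limits_keep_all_frames(self, rng):
        z = rng.standard_normal(100)
        sel = select_active_frames(z, np.zeros(100), z_threshold=-np.inf,
                                   fd_threshold=np.inf)
        assert sel.n_retained == 100

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            select_active_frames(rng.standard_normal(5), np.zeros(6))


class TestPcaReduce:
    def test_exact_low_rank_recovered(self, rng):
        basis = rng.standard_normal((3, 40))
        frames = rng.standard_normal((50, 3)) @ basis
        model, reduced = pca_reduce(frames, variance_target=0.9)
        assert model.n_components == 3
        recon = model.inverse_transform(reduced)
        assert np.allclose(recon, frames, atol=1e-8)

    def test_full_variance_target_is_identity(self, rng):
        frames = rng.standard_normal((20, 10))
        model, reduced = pca_reduce(frames, variance_target=1.0)
        assert np.allclose(model.inverse_transform(reduced), frames, atol=1e-8)

    def test_orthonormal_components(self, rng):
        model, _ = pca_reduce(rng.standard_normal((30, 15)), 0.8)
        G = model.components @ model.components.T
        assert np.allclose(G, np.eye(model.n_components), atol=1e-8)

    def test_matches_covariance_eigensolve_oracle(self, rng):
        frames = rng.standard_normal((60, 12))
        model, _ = pca_reduce(frames, variance_target=1.0)
        C = np.cov(frames, rowvar=False, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        expected = evals / evals.sum()
        assert np.allclose(
            model.explained_variance_fractions, expected[: model.n_components], atol=1e-8
        )

    def test_invalid_target_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(rng.standard_normal((10, 4)), variance_target=0.0)
        with pytest.raises(ValueError):
            pca_reduce(rng.standard_normal((10, 4)), variance_target=1.5)


class TestConsensus:
    def test_separated_clouds_perfectly_stable(self, rng):
        X = np.concatenate(
            [rng.normal(0, 0.05, size=(30, 2)), rng.normal(5, 0.05, size=(30, 2))]
        )
        report = consensus_cluster(X, k_range=(2,), n_resamples=40, rng=rng)
        C = report.consensus_matrices[2]
        finite = C[np.isfinite(C)]
        assert np.all((finite > 0.99) | (finite < 0.01))
        assert report.pac[2] == 0.0

    def test_fully_ambiguous_consensus_gives_pac_one(self):
        C = np.full((10, 10), 0.5)
        np.fill_diagonal(C, 1.0)
        assert pac_from_consensus(C) == 1.0

    def test_three_planted_clusters_selected(self, rng):
        centers = np.array([[0, 0], [4, 0], [2, 3.5]], dtype=float)
        X = np.concatenate([rng.normal(c, 0.5, size=(40, 2)) for c in centers])
        report = consensus_cluster(X, k_range=(2, 3, 4, 5), n_resamples=50, rng=rng)
        assert report.k_optimal == 3

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            consensus_cluster(rng.standard_normal((30, 2)), k_range=(4,), rng=rng)


class TestClusterCaps:
    def test_point_masses_zero_inertia(self, rng):
        pts = np.array([[0.0, 0.0], [5.0, 5.0], [-5.0, 5.0]])
        X = np.repeat(pts, 10, axis=0)
        labels = cluster_caps(X, 3, rng=rng)
        # zero inertia: every member equals its cluster mean
        for k in (1, 2, 3):
            members = X[labels == k]
            assert np.allclose(members, members.mean(axis=0))

    def test_labels_stable_across_seeds(self, rng):
        X = np.concatenate(
            [rng.normal(0, 0.1, (25, 3)), rng.normal(4, 0.1, (40, 3))]
        )
        a = cluster_caps(X, 2, rng=np.random.default_rng(1))
        b = cluster_caps(X, 2, rng=np.random.default_rng(99))
        assert np.array_equal(a, b)  # renumbering by size makes this canonical

    def test_renumbered_by_descending_size(self, rng):
        X = np.concatenate([rng.normal(0, 0.1, (50, 2)), rng.normal(6, 0.1, (10, 2))])
        labels = cluster_caps(X, 2, rng=rng)
        assert np.sum(labels == 1) > np.sum(labels == 2)

    def test_best_inertia_matches_bruteforce_partition(self, rng):
        X = rng.standard_normal((12, 2))
        labels = cluster_caps(X, 2, n_repeats=50, rng=rng)

        def inertia(mask):
            a, b = X[mask], X[~mask]
            return sum(
                ((g - g.mean(axis=0)) ** 2).sum() for g in (a, b) if len(g)
            )

        best = min(
            inertia(np.array(bits, dtype=bool))
            for bits in itertools.product([False, True], repeat=12)
            if 0 < sum(bits) < 12
        )
        assert inertia(labels == 1) == pytest.approx(best, rel=1e-9)

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_caps(rng.standard_normal((10, 2)), 1, rng=rng)


class TestCapMaps:
    def test_identical_member_frames(self, rng):
        v = rng.standard_normal(30)
        w = rng.standard_normal(30)
        frames = np.concatenate([np.tile(v, (5, 1)), np.tile(w, (5, 1))])
        model, _ = pca_reduce(frames, variance_target=1.0)
        labels = np.array([1] * 5 + [2] * 5)
        caps = build_cap_maps(frames, labels, model)
        zv = (v - v.mean()) / v.std()
        assert np.allclose(caps.maps[0], zv, atol=1e-6)
        assert caps.match_thresholds[0] == pytest.approx(1.0, abs=1e-9)

    def test_zscore_contract(self, tiny_study):
        maps = tiny_study.cap_set.maps
        assert np.allclose(maps.mean(axis=1), 0.0, atol=1e-8)
        assert np.allclose(maps.std(axis=1), 1.0, atol=1e-8)

    def test_small_cluster_rejected(self, rng):
        frames = rng.standard_normal((5, 10))
        model, _ = pca_reduce(frames, 1.0)
        with pytest.raises(ValueError):
            build_cap_maps(frames, np.array([1, 1, 1, 1, 2]), model)

    def test_voxel_permutation_equivariance(self, rng):
        frames = rng.standard_normal((40, 20)) + np.repeat(
            rng.standard_normal((2, 20)) * 3, 20, axis=0
        )
        labels = np.array([1] * 20 + [2] * 20)
        perm = rng.permutation(20)
        model, _ = pca_reduce(frames, 1.0)
        caps = build_cap_maps(frames, labels, model)
        model_p, _ = pca_reduce(frames[:, perm], 1.0)
        caps_p = build_cap_maps(frames[:, perm], labels, model_p)
        assert np.allclose(caps_p.maps, caps.maps[:, perm], atol=1e-8)


class TestFrameMatching:
    def _capset(self, rng, n_vox=40, k=3):
        frames = []
        labels = []
        for i in range(k):
            base = rng.standard_normal(n_vox) * 2
            frames.append(base + rng.normal(0, 0.3, size=(20, n_vox)))
            labels.extend([i + 1] * 20)
        frames = np.concatenate(frames)
        model, _ = pca_reduce(frames, 0.99)
        return build_cap_maps(frames, np.array(labels), model), frames

    def test_exact_map_frame_assigned(self, rng):
        caps, _ = self._capset(rng)
        labels = match_frames_to_caps(caps.maps[1][None, :], caps)
        assert labels[0] == 2

    def test_anticorrelated_frame_unassigned(self, rng):
        caps, _ = self._capset(rng)
        assert caps.match_thresholds.min() > 0
        frame = -caps.maps.sum(axis=0)
        assert match_frames_to_caps(frame[None, :], caps)[0] == UNASSIGNED

    def test_zero_variance_frame_unassigned_with_warning(self, rng):
        caps, _ = self._capset(rng)
        with pytest.warns(UserWarning):
            labels = match_frames_to_caps(np.zeros((1, 40)), caps)
        assert labels[0] == UNASSIGNED

    def test_reference_self_consistency(self, rng):
        # re-matching the reference frames reproduces their cluster labels
        caps, frames = self._capset(rng)
        true = np.concatenate([[k + 1] * 20 for k in range(3)])
        matched = match_frames_to_caps(frames, caps)
        agree = np.mean(matched == true)
        assert agree >= 0.95

    def test_volume_series_expansion(self, rng):
        z = np.array([1.0, 0.0, 2.0, 0.0, 3.0])
        sel = select_active_frames(z, np.zeros(5), z_threshold=0.5)
        series = labels_to_volume_series(5, sel, np.array([2, UNASSIGNED, 1]))
        assert series.tolist() == [2, -1, 0, -1, 1]


class TestNetworkOverlap:
    def test_single_network_positive_tail(self):
        atlas = np.repeat([1, 2, 3], 10)
        cap = np.zeros(30)
        cap[atlas == 3] = 2.0
        table = network_overlap(cap, atlas, z_cut=1.0)
        assert table.loc[3, "positive"] == 100.0
        assert table["negative"].sum() == 0.0

    def test_negation_swaps_tails(self, rng):
        atlas = np.repeat(np.arange(1, 6), 20)
        cap = rng.standard_normal(100)
        a = network_overlap(cap, atlas, 1.0)
        b = network_overlap(-cap, atlas, 1.0)
        assert np.allclose(a["positive"], b["negative"])
        assert np.allclose(a["negative"], b["positive"])

    def test_gaussian_tail_fraction(self, rng):
        n = 100_000
        atlas = np.ones(n, dtype=int)
        cap = rng.standard_normal(n)
        frac_pos = np.mean(cap > 1.04)
        assert frac_pos == pytest.approx(1 - norm.cdf(1.04), abs=0.01)
        table = network_overlap(cap, atlas, 1.04)
        assert table.loc[1, "positive"] == 100.0

    def test_seed_exclusion(self):
        atlas = np.array([1, 1, 2, 2])
        cap = np.array([5.0, 0.0, 5.0, 0.0])
        table = network_overlap(cap, atlas, 1.0, exclude=np.array([0]))
        assert table.loc[2, "positive"] == 100.0
        assert table.loc[1, "positive"] == 0.0
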