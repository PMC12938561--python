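"""Patch extraction, similarity, message passing, hierarchy and selection."""

import numpy as np
import pytest

from conftest import make_blobs
from glioseg.phantom import generate_phantom
from glioseg.preprocess import percentile_normalize
from glioseg.upoap import (
    APConfig, MessageState, Partition, PatchFeatureSet,
    ap_step, build_similarity, compute_preferences, extract_patches,
    hierarchical_refine, levine_nazif_score, masked_features, run_upoap,
    select_exemplars, select_optimal_partition,
)
from glioseg.volume_io import BinaryMask, MultiModalVolume


def tiny_volume(shape=(12, 12, 12), seed=0):
    rng = np.random.default_rng(seed)
    data = {m: rng.random(shape) + 0.1 for m in ("T1", "T1ce", "T2", "FLAIR")}
    return MultiModalVolume(data)


class TestExtractPatches:
    def test_single_voxel_mask(self):
        vol = tiny_volume()
        mask = np.zeros(vol.shape, dtype=bool)
        mask[5, 6, 7] = True
        patches = extract_patches(vol, BinaryMask(mask))
        assert len(patches) == 1
        assert len(patches[0]) == 1
        np.testing.assert_array_equal(patches[0].coords, [[5, 6, 7]])

    def test_patch_count_matches_tiling_oracle(self):
        vol = tiny_volume()
        mask = np.zeros(vol.shape, dtype=bool)
        mask[1:11, 1:11, 1:11] = True  # 10^3 all-true block
        cfg = APConfig()  # patch 5, stride 2
        patches = extract_patches(vol, BinaryMask(mask), cfg)

        def origins(extent, p, stride):
            last = max(0, extent - p)
            o = list(range(0, last + 1, stride))
            if o[-1] != last:
                o.append(last)
            return o

        count = 0
        for ox in origins(10, 5, 2):
            for oy in origins(10, 5, 2):
                for oz in origins(10, 5, 2):
                    count += 1  # every window holds masked voxels here
        assert len(patches) == count

    def test_every_masked_voxel_is_covered(self):
        vol = tiny_volume()
        rng = np.random.default_rng(3)
        mask = rng.random(vol.shape) < 0.2
        mask[6, 6, 6] = True
        patches = extract_patches(vol, BinaryMask(mask))
        covered = np.concatenate([p.voxel_indices for p in patches])
        assert set(covered) == set(range(int(mask.sum())))

    def test_features_are_zscored_per_modality(self):
        vol = tiny_volume()
        mask = np.ones(vol.shape, dtype=bool)
        _, feats, sigmas = masked_features(vol, BinaryMask(mask))
        np.testing.assert_allclose(feats.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(feats.var(axis=0), 1.0, atol=1e-8)
        np.testing.assert_array_equal(sigmas, np.ones(4))

    def test_empty_mask_rejected(self):
        vol = tiny_volume()
        with pytest.raises(ValueError, match="empty"):
            extract_patches(vol, BinaryMask(np.zeros(vol.shape, dtype=bool)))


class TestSimilarity:
    def test_identical_points_have_maximal_similarity(self):
        feats = np.tile([0.3, 0.5, 0.1, 0.9], (4, 1))
        S = build_similarity(feats, sigmas=np.ones(4))
        np.testing.assert_allclose(S, 0.0, atol=1e-12)

    def test_one_sigma_per_modality_sums_to_minus_B(self):
        """Points one scale-unit apart in each of 4 modalities score -4."""
        sigmas = np.array([0.5, 1.0, 2.0, 4.0])
        feats = np.array([[0.0, 0, 0, 0], sigmas])
        S = build_similarity(feats, sigmas=sigmas)
        # brute-force check of the same pair
        want = -sum(abs(feats[0][b] - feats[1][b]) / sigmas[b] for b in range(4))
        assert S[0, 1] == pytest.approx(-4.0, abs=1e-12)
        assert S[0, 1] == pytest.approx(want, abs=1e-12)

    def test_symmetry_on_random_inputs(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(30, 4))
        S = build_similarity(feats)
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        assert np.all(np.diag(S) == 0.0)

    def test_zero_scale_modality_dropped(self, caplog):
        feats = np.array([[0.0, 1.0], [1.0, 1.0]])  # modality 2 constant
        S = build_similarity(feats, sigmas=np.array([1.0, 0.0]))
        assert S[0, 1] == pytest.approx(-1.0)


class TestPreferences:
    def test_row_mean_of_two_point_matrix(self):
        S = np.array([[0.0, -2.0], [-2.0, 0.0]])
        np.testing.assert_allclose(compute_preferences(S, "row_mean"), [-1.0, -1.0])

    def test_constant_offdiagonal_median(self):
        S = -3.0 * (1 - np.eye(5))
        np.testing.assert_allclose(compute_preferences(S, "median_similarity"),
                                   np.full(5, -3.0))

    def test_row_mean_matches_bruteforce_row_average(self):
        rng = np.random.default_rng(0)
        D = rng.random((10, 10))
        S = -(D + D.T) / 2
        np.fill_diagonal(S, 0.0)
        want = [sum(S[i, k] for k in range(10)) / 10 for i in range(10)]
        np.testing.assert_allclose(compute_preferences(S, "row_mean"), want, atol=1e-12)


class TestApStep:
    def test_first_step_matches_hand_computed_two_point_oracle(self):
        """One update from the zero state on L=2, worked by hand.

        S = [[0,-2],[-2,0]], row-mean preferences (-1,-1):
        responsibilities r = [[1,-1],[-1,1]] (each point prefers itself);
        smoothed over the 4-window with zero-initialized history,
        r_hat = r/4; both availability terms vanish (no positive support,
        positive self-responsibility is capped at zero).
        """
        S = np.array([[0.0, -2.0], [-2.0, 0.0]])
        pref = compute_preferences(S, "row_mean")
        state = ap_step(MessageState.zeros(2), S, pref)
        np.testing.assert_allclose(state.r, [[1.0, -1.0], [-1.0, 1.0]], atol=1e-12)
        np.testing.assert_allclose(state.a, 0.0, atol=1e-12)
        np.testing.assert_allclose(state.r_hat, [[0.25, -0.25], [-0.25, 0.25]],
                                   atol=1e-12)
        np.testing.assert_allclose(state.a_hat, 0.0, atol=1e-12)

    def test_stationary_messages_equal_smoothed(self):
        """At a message fixed point, smoothed and raw messages coincide.

        (r*, a*) = ([[1,-1],[-1,1]], 0) is the fixed point of the 2-point
        problem above: seeding the history with it, one further update
        reproduces it exactly and the moving average equals the raw values.
        """
        S = np.array([[0.0, -2.0], [-2.0, 0.0]])
        pref = compute_preferences(S, "row_mean")
        r_star = np.array([[1.0, -1.0], [-1.0, 1.0]])
        a_star = np.zeros((2, 2))
        state = MessageState(r=r_star.copy(), a=a_star.copy(),
                             r_hat=r_star.copy(), a_hat=a_star.copy(),
                             history=[(r_star.copy(), a_star.copy())] * 3)
        nxt = ap_step(state, S, pref)
        np.testing.assert_allclose(nxt.r, r_star, atol=1e-12)
        np.testing.assert_allclose(nxt.a, a_star, atol=1e-12)
        np.testing.assert_allclose(nxt.r_hat, nxt.r, atol=1e-12)
        np.testing.assert_allclose(nxt.a_hat, nxt.a, atol=1e-12)
        # and the messages converge toward that fixed point from zero
        state = MessageState.zeros(2)
        for _ in range(80):
            state = ap_step(state, S, pref)
        np.testing.assert_allclose(state.r_hat, r_star, atol=1e-4)

    def test_history_buffer_never_exceeds_window(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(10, 4))
        S = build_similarity(feats)
        pref = compute_preferences(S)
        state = MessageState.zeros(10)
        for _ in range(12):
            state = ap_step(state, S, pref)
            assert len(state.history) <= 4

    def test_non_finite_message_raises_with_iteration(self):
        S = np.array([[0.0, -np.inf], [-np.inf, 0.0]])
        with pytest.raises(FloatingPointError, match="iteration 1"):
            ap_step(MessageState.zeros(2), S, np.array([-1.0, -1.0]))


class TestSelectExemplars:
    def test_single_point_is_its_own_exemplar(self):
        part = run_upoap(np.zeros((1, 4)), sigmas=np.ones(4))
        assert part.n_clusters == 1
        assert part.exemplars[0] == 0

    def test_tie_broken_toward_lowest_index(self):
        state = MessageState.zeros(6)
        # identical evidence rows: candidates 2 and 5 tie everywhere
        ev = np.full((6, 6), -1.0)
        ev[:, 2] = ev[:, 5] = 0.0
        state.r_hat = ev
        part = select_exemplars(state, np.zeros((6, 6)))
        assert 2 in part.exemplars.tolist()
        assert np.all(part.assignment == part.assignment[0])

    def test_two_separated_blobs_match_reference_clustering(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.01, (3, 4)), rng.normal(3, 0.01, (3, 4))])
        part = run_upoap(X, sigmas=np.ones(4))
        assert part.n_clusters == 2
        assert len(set(part.assignment[:3])) == 1
        assert len(set(part.assignment[3:])) == 1
        # independent reference: scikit-learn affinity propagation
        from sklearn.cluster import AffinityPropagation
        from sklearn.metrics import adjusted_rand_score
        ref = AffinityPropagation(random_state=0).fit(X)
        assert adjusted_rand_score(ref.labels_, part.assignment) == 1.0

    def test_exemplars_belong_to_their_own_cluster(self):
        X, _ = make_blobs(0)
        part = run_upoap(X, sigmas=np.ones(4))
        for c, e in enumerate(part.exemplars):
            assert part.assignment[e] == c


class TestRunUpoap:
    def test_deterministic_across_runs(self):
        X, _ = make_blobs(3)
        p1 = run_upoap(X, sigmas=np.ones(4))
        p2 = run_upoap(X, sigmas=np.ones(4))
        np.testing.assert_array_equal(p1.assignment, p2.assignment)
        np.testing.assert_array_equal(p1.exemplars, p2.exemplars)

    def test_blob_recovery_across_generator_seeds(self):
        """Three tight 4-D blobs: exactly 3 clusters, ARI >= 0.9."""
        from sklearn.metrics import adjusted_rand_score
        good = 0
        for seed in range(20):
            X, y = make_blobs(seed)
            part = run_upoap(X, sigmas=np.ones(4))
            if part.n_clusters == 3 and \
                    adjusted_rand_score(y, part.assignment) >= 0.9:
                good += 1
        assert good >= 19  # >= 95% of seeds

    def test_two_identical_points_form_single_cluster(self):
        part = run_upoap(np.zeros((2, 4)), sigmas=np.ones(4))
        assert part.n_clusters == 1


def _patches_from_points(features, groups):
    """Helper: wrap disjoint point groups as patches with given partitions."""
    patches, parts = [], []
    for pid, (idx, assignment, exemplars) in enumerate(groups):
        idx = np.asarray(idx)
        patches.append(PatchFeatureSet(voxel_indices=idx,
                                       coords=np.zeros((idx.size, 3)),
                                       features=features[idx], patch_id=pid,
                                       sigmas=np.ones(features.shape[1])))
        parts.append(Partition(assignment=np.asarray(assignment),
                               exemplars=np.asarray(exemplars), level=1))
    return parts, patches


class TestHierarchy:
    def test_redundant_exemplars_merge_to_three_blobs(self):
        """6 exemplars, drawn 2 per blob, collapse to exactly 3 clusters."""
        X, y = make_blobs(0)
        # two patches, each holding half of every blob and 3 exemplars
        idx_a = np.concatenate([np.arange(0, 10), np.arange(20, 30), np.arange(40, 50)])
        idx_b = np.concatenate([np.arange(10, 20), np.arange(30, 40), np.arange(50, 60)])
        assign = np.repeat([0, 1, 2], 10)
        parts, patches = _patches_from_points(X, [
            (idx_a, assign, [0, 10, 20]),   # local exemplar indices
            (idx_b, assign, [0, 10, 20]),
        ])
        candidates = hierarchical_refine(parts, patches, X, APConfig(),
                                         sigmas=np.ones(4))
        top = candidates[-1]
        assert top.n_clusters == 3
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(y, top.assignment) == 1.0

    def test_cluster_count_never_increases_with_level(self):
        X, _ = make_blobs(1, n_per=30)
        cfg = APConfig()
        # four overlapping patches clustered for real
        idx = [np.arange(0, 50), np.arange(40, 90), np.arange(25, 75),
               np.arange(0, 90)]
        parts, patches = [], []
        for pid, ix in enumerate(idx):
            p = PatchFeatureSet(voxel_indices=ix, coords=np.zeros((ix.size, 3)),
                                features=X[ix], patch_id=pid, sigmas=np.ones(4))
            patches.append(p)
            parts.append(run_upoap(p, cfg))
        candidates = hierarchical_refine(parts, patches, X, cfg, sigmas=np.ones(4))
        ks = [c.n_clusters for c in candidates]
        assert all(k2 <= k1 for k1, k2 in zip(ks, ks[1:]))
        assert candidates[-1].level <= cfg.max_hierarchy_levels

    def test_single_cluster_passes_through_unchanged(self):
        X = np.zeros((10, 4))
        parts, patches = _patches_from_points(
            X, [(np.arange(10), np.zeros(10, dtype=int), [0])])
        candidates = hierarchical_refine(parts, patches, X, APConfig(),
                                         sigmas=np.ones(4))
        for c in candidates:
            assert c.n_clusters == 1


class TestPartitionSelection:
    def test_degenerate_single_cluster_scores_zero(self):
        X = np.zeros((5, 4))
        part = Partition(assignment=np.zeros(5, dtype=int), exemplars=[0])
        assert levine_nazif_score(part, X, np.ones(4)) == 0.0

    def test_hand_computed_two_cluster_score(self):
        """4 points on a line, 2 clusters: intra=0.1, inter=1 -> 1/1.1."""
        X = np.array([[0.0], [0.2], [1.0], [1.2]])
        part = Partition(assignment=np.array([0, 0, 1, 1]), exemplars=[0, 2])
        score = levine_nazif_score(part, X, np.ones(1))
        assert score == pytest.approx(1.0 / 1.1, abs=1e-12)

    def test_true_blob_partition_beats_single_cluster_merge(self):
        X, y = make_blobs(0)
        exemplars = [0, 20, 40]
        true = Partition(assignment=np.repeat([0, 1, 2], 20), exemplars=exemplars)
        merged = Partition(assignment=np.zeros(60, dtype=int), exemplars=[0])
        assert levine_nazif_score(true, X, np.ones(4)) > \
            levine_nazif_score(merged, X, np.ones(4))

    def test_argmax_and_tie_rules(self):
        X, _ = make_blobs(0)
        good = Partition(assignment=np.repeat([0, 1, 2], 20), exemplars=[0, 20, 40],
                         level=2)
        bad = Partition(assignment=np.zeros(60, dtype=int), exemplars=[0], level=1)
        assert select_optimal_partition([bad, good, bad], X, np.ones(4)) is good
        # exact tie -> earliest (shallowest) candidate
        assert select_optimal_partition([bad, bad], X, np.ones(4)) is bad
        with pytest.raises(ValueError, match="empty"):
            select_optimal_partition([], X)


def test_stage2_features_separate_on_phantom(small_spec):
    """Masked multi-modal features separate the three lesion compartments."""
    volume, gt = generate_phantom(small_spec)
    normed = volume.with_data({m: percentile_normalize(volume.data[m])
                               for m in volume.modalities})
    mask = BinaryMask(gt.data > 0)
    coords, feats, _ = masked_features(normed, mask)
    codes = gt.data[tuple(coords.T)]
    centroids = np.array([feats[codes == c].mean(axis=0) for c in (1, 2, 3)])
    from scipy.spatial.distance import pdist
    assert pdist(centroids, metric="cityblock").min() > 1.0
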