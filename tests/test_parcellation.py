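"""k-means parcellation (with exhaustive-partition oracle), label
harmonization (with permutation oracle), consensus maps and pattern checks."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from connparc.connectivity import CrossCorrelationMatrix, build_ccm, build_connectivity_matrix
from connparc.parcellation import (
    ConnectivityParcellator,
    ConsensusLabeler,
    SubjectParcellation,
    build_consensus,
    classify_pattern,
    cluster_volumes,
    consensus_ari,
    harmonize_labels,
    kmeans_parcellate,
)
from connparc.phantom import generate_cohort
from conftest import small_phantom_config


def exhaustive_kmeans_optimum(X: np.ndarray, k: int) -> float:
    """Global optimum of the k-means objective by enumerating every
    assignment of points to k nonempty groups."""
    n = len(X)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.asarray(labels)
        if len(set(labels.tolist())) < k:
            continue
        inertia = 0.0
        for c in range(k):
            pts = X[labels == c]
            inertia += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, inertia)
    return best


def random_ccm(rng, n):
    counts = rng.integers(0, 400, size=(n, 5)).astype(float)
    counts += rng.random((n, 5))  # avoid constant rows
    c = np.corrcoef(counts)
    np.fill_diagonal(c, 1.0)
    return CrossCorrelationMatrix(
        subject_id="s", ccm=c, used_voxels=np.arange(n), excluded_voxels={}
    )


def make_parc(labels, k, fingerprints=None, affine=None, coords=None, sid="s"):
    labels = np.asarray(labels, dtype=np.int16)
    if coords is None:
        coords = np.column_stack(
            [np.arange(len(labels)), np.zeros(len(labels), int), np.zeros(len(labels), int)]
        )
    return SubjectParcellation(
        subject_id=sid, seed_voxel_index=coords, labels=labels, k=k,
        inertia=0.0, affine=affine, cluster_fingerprints=fingerprints,
    )


class TestKMeansParcellate:
    def test_perfect_blocks_recovered(self):
        blocks = np.repeat(np.arange(3), 4)
        c = np.where(blocks[:, None] == blocks[None, :], 1.0, -0.5)
        ccm = CrossCorrelationMatrix("s", c, np.arange(12), {})
        parc = kmeans_parcellate(ccm, k=3, seed=0, restarts=10)
        assert adjusted_rand_score(blocks, parc.labels) == 1.0

    def test_k1_inertia_is_total_scatter(self, rng):
        ccm = random_ccm(rng, 6)
        parc = kmeans_parcellate(ccm, k=1, seed=0)
        assert np.all(parc.labels == 1)
        scatter = ((ccm.ccm - ccm.ccm.mean(axis=0)) ** 2).sum()
        assert parc.inertia == pytest.approx(scatter, rel=1e-10)

    @pytest.mark.parametrize("n", [8, 9])
    def test_inertia_matches_exhaustive_partition_optimum(self, rng, n):
        ccm = random_ccm(rng, n)
        parc = kmeans_parcellate(ccm, k=3, seed=0, restarts=50)
        assert parc.inertia == pytest.approx(
            exhaustive_kmeans_optimum(ccm.ccm, 3), rel=1e-9
        )

    def test_k_exceeding_voxels_raises(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_parcellate(random_ccm(rng, 4), k=5)

    def test_deterministic_given_seed(self, rng):
        ccm = random_ccm(rng, 20)
        a = kmeans_parcellate(ccm, k=3, seed=42, restarts=5)
        b = kmeans_parcellate(ccm, k=3, seed=42, restarts=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_estimator_excludes_constant_fingerprints(self):
        X = np.array([[1, 2, 3], [3, 2, 1], [5, 5, 5], [2, 2, 4], [1, 4, 1]], float)
        est = ConnectivityParcellator(n_clusters=2, random_state=0).fit(X)
        assert est.labels_[2] == -1
        assert set(est.labels_[[0, 1, 3, 4]]) <= {0, 1}


class TestHarmonize:
    def _pair_with_permuted_labels(self):
        fp = np.array([[100.0, 10, 5], [10, 100, 5], [5, 10, 100]])
        labels_a = np.array([1, 1, 2, 2, 3, 3])
        perm_map = {1: 3, 2: 1, 3: 2}
        labels_b = np.array([perm_map[c] for c in labels_a])
        a = make_parc(labels_a, 3, fingerprints=fp, sid="a")
        b = make_parc(labels_b, 3, fingerprints=fp[[1, 2, 0]], sid="b")
        return a, b

    def test_label_permutation_is_undone(self):
        a, b = self._pair_with_permuted_labels()
        ha, hb = harmonize_labels([a, b])
        np.testing.assert_array_equal(ha.labels, hb.labels)

    def test_aligned_subject_keeps_identity(self):
        fp = np.array([[100.0, 10, 5], [10, 100, 5], [5, 10, 100]])
        a = make_parc([1, 1, 2, 3], 3, fingerprints=fp, sid="a")
        (h,) = harmonize_labels([a], reference=fp)
        np.testing.assert_array_equal(h.labels, a.labels)

    def test_assignment_cost_matches_permutation_oracle(self, rng):
        """Hungarian choice equals the best of all k! permutations."""
        for _ in range(3):
            fp = rng.random((3, 4)) * 100 + 1
            ref = rng.random((3, 4)) * 100 + 1
            parc = make_parc([1, 2, 3], 3, fingerprints=fp)
            (h,) = harmonize_labels([parc], reference=ref)
            chosen = np.array([h.labels[i] for i in range(3)]) - 1

            def cost_of(perm):
                a = fp / fp.sum(axis=1, keepdims=True)
                b = ref / ref.sum(axis=1, keepdims=True)
                return sum(((a[i] - b[perm[i]]) ** 2).sum() for i in range(3))

            best = min(cost_of(p) for p in itertools.permutations(range(3)))
            assert cost_of(tuple(chosen)) == pytest.approx(best, rel=1e-12)

    def test_idempotent(self, small_parcellations):
        _, _, _, parcs = small_parcellations
        once = harmonize_labels(parcs)
        twice = harmonize_labels(once)
        for a, b in zip(once, twice):
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_anatomical_x_ranks_medial_to_lateral(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        labels = [2, 2, 1, 1]  # label 1 sits lateral, 2 medial
        p = make_parc(labels, 2, affine=np.eye(4), coords=coords)
        (h,) = harmonize_labels([p], reference="anatomical-x")
        np.testing.assert_array_equal(h.labels, [1, 1, 2, 2])

    def test_mismatched_k_raises(self):
        a = make_parc([1, 2], 2)
        b = make_parc([1, 2, 3], 3)
        with pytest.raises(ValueError, match="disagree"):
            harmonize_labels([a, b])


class TestConsensus:
    def test_majority_voxel_joins_final_cluster(self):
        # label 1 in 100 of 168 subjects at one voxel: 100 >= ceil(0.5*168)=84
        stack = np.zeros((168, 1, 1, 1), dtype=np.int16)
        stack[:100] = 1
        est = ConsensusLabeler(0.5).fit(stack)
        assert est.counts_[0, 0, 0, 0] == 100
        assert est.final_labels_[0, 0, 0] == 1

    def test_threshold_boundary_inclusive(self):
        # counts (2,1,1) of 4 subjects, threshold 0.5 -> 2 >= 2 passes
        stack = np.array([1, 1, 2, 3], dtype=np.int16).reshape(4, 1, 1, 1)
        est = ConsensusLabeler(0.5).fit(stack)
        assert est.final_labels_[0, 0, 0] == 1

    def test_highest_count_wins_overlap(self):
        # counts (90, 95) of 168: both eligible, cluster 2 has more subjects
        stack = np.zeros((185, 1, 1, 1), dtype=np.int16)
        stack[:90] = 1
        stack[90:] = 2
        est = ConsensusLabeler(90 / 185).fit(stack)
        assert est.counts_[0, 0, 0, 0] == 90 and est.counts_[1, 0, 0, 0] == 95
        assert est.final_labels_[0, 0, 0] == 2

    def test_final_masks_disjoint_and_counts_bounded(self, small_parcellations):
        _, gt, _, parcs = small_parcellations
        cons = build_consensus(parcs, grid_shape=gt.label_volume.shape)
        assert cons.counts.max() <= cons.n_subjects
        per_voxel = np.sum(
            [cons.final_labels == c for c in range(1, cons.k + 1)], axis=0
        )
        assert per_voxel.max() <= 1

    def test_subject_order_invariance(self, small_parcellations):
        _, gt, _, parcs = small_parcellations
        a = build_consensus(parcs, grid_shape=gt.label_volume.shape)
        b = build_consensus(parcs[::-1], grid_shape=gt.label_volume.shape)
        np.testing.assert_array_equal(a.final_labels, b.final_labels)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestPatternAndVolumes:
    def test_truth_slabs_flagged_mediolateral(self, small_cohort):
        _, gt, _ = small_cohort
        res = classify_pattern(gt.label_volume, gt.affine, k=3)
        assert res.is_mediolateral

    def test_interleaved_labels_fail_contiguity(self):
        vol = np.zeros((6, 1, 1), dtype=int)
        vol[:, 0, 0] = [1, 2, 1, 2, 1, 2]
        res = classify_pattern(vol, np.eye(4), k=2)
        assert not res.is_mediolateral
        assert not res.contiguous["right"].all()

    def test_absent_cluster_fails_when_k_given(self):
        vol = np.zeros((4, 1, 1), dtype=int)
        vol[:2, 0, 0] = 1
        vol[2:, 0, 0] = 2
        assert classify_pattern(vol, np.eye(4), k=3).is_mediolateral is False

    @pytest.mark.parametrize(
        "n_vox,voxel_mm,expected",
        [(10, 1.0, 10.0), (100, 1.25, 195.3125), (0, 2.0, 0.0)],
    )
    def test_cluster_volume_arithmetic(self, n_vox, voxel_mm, expected):
        labels = np.zeros((200, 1, 1), dtype=int)
        labels[:n_vox, 0, 0] = 1
        affine = np.diag([voxel_mm] * 3 + [1.0])
        assert cluster_volumes(labels, affine, k=1)[0] == pytest.approx(expected)


def test_noiseless_cohort_recovers_truth_exactly():
    """End-to-end parameter recovery in the noiseless, jitter-free limit."""
    cfg = small_phantom_config(profile_noise=0.0, jitter_sd=0.0, n_subjects=3)
    gt, subjects = generate_cohort(cfg)
    parcs = []
    for i, s in enumerate(subjects):
        cm = build_connectivity_matrix(
            s.count_volumes, s.seed_mask, s.target_names,
            affines=[s.affine] * len(s.target_names), subject_id=s.subject_id,
        )
        parcs.append(kmeans_parcellate(build_ccm(cm), k=3, seed=i, restarts=10, cm=cm))
    cons = build_consensus(harmonize_labels(parcs), grid_shape=gt.label_volume.shape)
    assert consensus_ari(cons.final_labels, gt.label_volume) == 1.0
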