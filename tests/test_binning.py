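"""Epitope binning: Ward clustering, k selection, PCA, asymmetry."""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from rabmab.binning import (
    CompetitionMatrix,
    Dendrogram,
    bin_epitopes,
    detect_asymmetry,
    normalize_matrix,
    pca_confirm,
    select_k,
    transpose_check,
    ward_cluster,
)
from rabmab.synthetic import CompetitionSimConfig, generate_competition


def brute_force_ward(points: np.ndarray):
    """Re-derive the Ward merge sequence from raw points at every step.

    Merge cost is the within-cluster variance increase
    2 * ni * nj / (ni + nj) * ||ci - cj||^2 recomputed from scratch; the
    height convention is its square root.  Tie-break by smallest leaf.
    """
    clusters: list[list[int]] = [[i] for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                first, second = sorted((ca, cb), key=min)
                na, nb = len(ca), len(cb)
                delta = (
                    2.0 * na * nb / (na + nb)
                    * np.sum((points[ca].mean(0) - points[cb].mean(0)) ** 2)
                )
                key = (delta, min(first), min(second))
                if best is None or key < best[0]:
                    best = (key, a, b, first, second)
        (delta, _, _), a, b, first, second = best
        merges.append((frozenset(first), frozenset(second), float(np.sqrt(delta))))
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def leaf_sets(dendrogram: Dendrogram):
    """Translate a Dendrogram's merge list into leaf-set pairs + heights."""
    members = {i: frozenset([i]) for i in range(dendrogram.n_leaves)}
    out = []
    for step, (left, right, height, _) in enumerate(dendrogram.merges):
        a, b = members[left], members[right]
        first, second = sorted((a, b), key=min)
        out.append((first, second, height))
        members[dendrogram.n_leaves + step] = a | b
    return out


class TestNormalize:
    def test_row_already_normalized(self):
        m = CompetitionMatrix(["a", "b", "c"], np.array(
            [[0.2, 1.0, 0.6], [1.0, 0.1, 0.5], [0.3, 0.4, 1.0]]
        ))
        norm = normalize_matrix(m)
        assert np.allclose(norm.values[0], [0.2, 1.0, 0.6])

    def test_row_scaled_by_max(self):
        m = CompetitionMatrix(["a", "b", "c"], np.array(
            [[1.0, 2.0, 4.0], [4.0, 1.0, 2.0], [2.0, 4.0, 1.0]]
        ))
        norm = normalize_matrix(m)
        assert np.allclose(norm.values[0], [0.25, 0.5, 1.0])

    def test_constant_row_rejected(self):
        m = CompetitionMatrix(["a", "b"], np.array([[0.5, 0.5], [0.1, 1.0]]))
        with pytest.raises(ValueError, match="a"):
            normalize_matrix(m)


class TestWardCluster:
    def test_identical_rows_merge_at_zero(self):
        x = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
        d = ward_cluster(x)
        assert d.merges[0][:3] == (0, 1, 0.0)

    def test_two_singletons_height_is_distance(self):
        d = ward_cluster(np.array([[0.0], [2.0]]))
        assert d.merges == [(0, 1, 2.0, 2)]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        for n in (4, 6, 8, 10):
            points = rng.normal(size=(n, 5))
            ours = leaf_sets(ward_cluster(points))
            oracle = brute_force_ward(points)
            for (a1, b1, h1), (a2, b2, h2) in zip(ours, oracle):
                assert {a1, b1} == {a2, b2}
                assert h1 == pytest.approx(h2, rel=1e-9)

    def test_heights_monotone_non_decreasing(self):
        rng = np.random.default_rng(32)
        for _ in range(5):
            d = ward_cluster(rng.normal(size=(12, 6)))
            heights = d.heights()
            assert np.all(np.diff(heights) >= -1e-12)

    def test_agrees_with_scipy_linkage(self):
        rng = np.random.default_rng(33)
        points = rng.normal(size=(15, 4))
        ours = ward_cluster(points)
        theirs = hierarchy.linkage(points, method="ward")
        assert np.allclose(np.sort(ours.heights()), np.sort(theirs[:, 2]))
        for k in (2, 3, 5):
            scipy_labels = hierarchy.fcluster(theirs, k, criterion="maxclust")
            assert adjusted_rand_score(ours.cut(k), scipy_labels) == pytest.approx(1.0)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            ward_cluster(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            ward_cluster(np.array([[np.nan, 1.0], [0.0, 1.0]]))


class TestSelectK:
    def test_largest_gap_before_final_merge(self):
        d = Dendrogram(n_leaves=4, merges=[(0, 1, 0.1, 2), (4, 2, 0.12, 3), (5, 3, 5.0, 4)])
        k, cut = select_k(d)
        assert k == 2
        assert cut == 5.0

    def test_equal_heights_give_single_cluster(self):
        d = Dendrogram(n_leaves=4, merges=[(0, 1, 1.0, 2), (4, 2, 1.0, 3), (5, 3, 1.0, 4)])
        assert select_k(d)[0] == 1

    def test_manual_override(self):
        d = Dendrogram(n_leaves=4, merges=[(0, 1, 0.1, 2), (4, 2, 0.12, 3), (5, 3, 5.0, 4)])
        assert select_k(d, k_override=3)[0] == 3

    def test_planted_six_groups_recovered(self):
        matrix, truth = generate_competition(
            CompetitionSimConfig(n_antibodies=16, n_groups=6, noise_sd=0.1, seed=3)
        )
        d = ward_cluster(normalize_matrix(matrix))
        k, _ = select_k(d)
        assert k == 6
        assert adjusted_rand_score(truth, d.cut(k)) == pytest.approx(1.0)


class TestPCAConfirm:
    def test_variance_shares_sorted_and_bounded(self):
        rng = np.random.default_rng(41)
        coords, ratios, _ = pca_confirm(rng.normal(size=(10, 6)))
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1.0 + 1e-9

    def test_duplicated_rows_identical_coordinates(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(6, 4))
        x[3] = x[0]
        coords, _, _ = pca_confirm(x)
        assert np.allclose(coords[0], coords[3])

    def test_full_rank_projection_preserves_distances(self):
        rng = np.random.default_rng(43)
        x = rng.normal(size=(8, 5))
        coords, ratios, _ = pca_confirm(x, n_components=5)
        assert np.allclose(pdist(coords), pdist(x - x.mean(0)), atol=1e-8)
        assert ratios.sum() == pytest.approx(1.0)

    def test_planted_groups_separate(self):
        matrix, truth = generate_competition(
            CompetitionSimConfig(n_antibodies=16, n_groups=6, noise_sd=0.1, seed=7)
        )
        _, _, separation = pca_confirm(normalize_matrix(matrix), labels=truth)
        assert separation > 1.0

    def test_rank_deficient_warns(self):
        x = np.zeros((5, 4))
        x[:, 0] = np.arange(5)
        with pytest.warns(RuntimeWarning):
            pca_confirm(x)


class TestTransposeCheck:
    def test_symmetric_matrix_full_agreement(self):
        matrix, _ = generate_competition(
            CompetitionSimConfig(n_groups=4, noise_sd=0.0, seed=1)
        )
        assert transpose_check(matrix) == pytest.approx(1.0)

    def test_mild_asymmetric_noise_high_agreement(self):
        matrix, _ = generate_competition(
            CompetitionSimConfig(n_groups=6, noise_sd=0.1, seed=5)
        )
        assert transpose_check(normalize_matrix(matrix)) >= 0.8

    def test_random_matrix_near_zero(self):
        rng = np.random.default_rng(51)
        matrix = CompetitionMatrix(
            [f"m{i}" for i in range(16)], rng.uniform(0.05, 1.0, size=(16, 16))
        )
        assert abs(transpose_check(matrix, k=4)) < 0.5


class TestDetectAsymmetry:
    def test_symmetric_matrix_empty(self):
        v = np.array([[0.1, 0.9], [0.9, 0.1]])
        assert detect_asymmetry(CompetitionMatrix(["a", "b"], v)) == []

    def test_flagged_pair_oriented_by_competition_direction(self):
        v = np.full((3, 3), 0.5)
        v[1, 2], v[2, 1] = 0.1, 0.9
        pairs = detect_asymmetry(CompetitionMatrix(["a", "b", "c"], v), margin=0.3)
        assert pairs == [("b", "c")]

    def test_unit_margin_never_flags_normalized(self):
        rng = np.random.default_rng(52)
        matrix, _ = generate_competition(CompetitionSimConfig(seed=4))
        norm = normalize_matrix(matrix)
        assert detect_asymmetry(norm, margin=1.0) == []

    def test_planted_asymmetric_binder_found(self):
        config = CompetitionSimConfig(
            n_groups=4, noise_sd=0.02, asymmetric_pairs=[(0, 1)], seed=9
        )
        matrix, _ = generate_competition(config)
        pairs = detect_asymmetry(normalize_matrix(matrix), margin=0.3)
        assert ("mab002", "mab001") in pairs or ("mab001", "mab002") in pairs


class TestBinEpitopes:
    def test_end_to_end_planted_recovery(self):
        matrix, truth = generate_competition(
            CompetitionSimConfig(n_antibodies=16, n_groups=6, noise_sd=0.1, seed=2)
        )
        groups = bin_epitopes(matrix)
        assert groups.k == 6
        assert adjusted_rand_score(truth, groups.labels) == pytest.approx(1.0)
        assert groups.separation is not None and groups.separation > 1.0
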