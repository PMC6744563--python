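"""Cosine-similarity matrix, UPGMA ordering, group extraction, occupancy."""

import numpy as np
import pytest

from msiclust.msdata_io import IonImage, ROI
from msiclust.simcluster import (
    MoleculeGroup,
    SimilarityMatrix,
    cosine_similarity_matrix,
    extract_groups,
    occupancy_table,
    order_by_clustering,
)


def _block_matrix(sizes, within, between):
    """Block-structured similarity matrix; scalar or per-pair `between`."""
    n = sum(sizes)
    sim = np.full((n, n), between, dtype=float)
    start = 0
    for size in sizes:
        sim[start : start + size, start : start + size] = within
        start += size
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(sim, [f"m{i}" for i in range(n)])


class TestCosineMatrix:
    def test_self_similarity_is_one(self, rng):
        X = rng.uniform(0, 1, size=(50, 3))
        sim = cosine_similarity_matrix(X)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)

    def test_disjoint_supports_have_zero_similarity(self):
        X = np.zeros((10, 2))
        X[:5, 0] = 1.0
        X[5:, 1] = 1.0
        sim = cosine_similarity_matrix(X)
        assert sim.values[0, 1] == 0.0

    def test_matches_direct_dot_products(self, rng):
        """Oracle: explicit normalized dot products."""
        X = rng.uniform(0, 2, size=(40, 5))
        sim = cosine_similarity_matrix(X)
        for i in range(5):
            for j in range(5):
                expected = X[:, i] @ X[:, j] / (
                    np.linalg.norm(X[:, i]) * np.linalg.norm(X[:, j])
                )
                assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_positive_scaling(self, rng):
        X = rng.uniform(0, 1, size=(30, 4))
        scaled = X * np.array([1e-3, 1.0, 40.0, 7.0])
        np.testing.assert_allclose(
            cosine_similarity_matrix(X).values,
            cosine_similarity_matrix(scaled).values,
            atol=1e-12,
        )

    def test_zero_norm_image_rejected_by_label(self):
        X = np.zeros((10, 2))
        X[:, 0] = 1.0
        with pytest.raises(ValueError, match="1"):
            cosine_similarity_matrix(X)

    def test_roi_restricts_pixels(self, rng):
        values = rng.uniform(0, 1, size=(4, 4))
        images = [
            IonImage(800.0, 0.004, values),
            IonImage(801.0, 0.004, values.T.copy()),
        ]
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2] = True
        sim = cosine_similarity_matrix(images, roi=ROI(mask))
        a = images[0].values[mask]
        b = images[1].values[mask]
        expected = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert sim.values[0, 1] == pytest.approx(expected, abs=1e-12)


class TestOrdering:
    def test_two_perfect_blocks_stay_contiguous(self):
        matrix = _block_matrix([4, 5], 1.0, 0.0)
        ordering, _ = order_by_clustering(matrix)
        labels = [0] * 4 + [1] * 5
        seen = [labels[i] for i in ordering]
        # one contiguous run per block
        changes = sum(a != b for a, b in zip(seen, seen[1:]))
        assert changes == 1

    def test_single_image_identity(self):
        matrix = SimilarityMatrix(np.array([[1.0]]), ["a"])
        ordering, Z = order_by_clustering(matrix)
        assert list(ordering) == [0]
        assert Z.shape == (0, 4)

    def test_merge_sequence_matches_hand_worked_upgma(self):
        """4-point UPGMA traced by hand: ab at 0.1, cd at 0.2, all at 0.8."""
        sim = np.array(
            [
                [1.0, 0.9, 0.2, 0.1],
                [0.9, 1.0, 0.3, 0.2],
                [0.2, 0.3, 1.0, 0.8],
                [0.1, 0.2, 0.8, 1.0],
            ]
        )
        matrix = SimilarityMatrix(sim, list("abcd"))
        _, Z = order_by_clustering(matrix)
        merges = [(int(r[0]), int(r[1]), round(r[2], 10), int(r[3])) for r in Z]
        assert merges == [
            (0, 1, 0.1, 2),
            (2, 3, 0.2, 2),
            (4, 5, 0.8, 4),  # mean of (0.8, 0.9, 0.7, 0.8) distances
        ]


class TestExtractGroups:
    def test_two_clean_blocks_extracted(self):
        matrix = _block_matrix([8, 9], 1.0, 0.0)
        ordering, _ = order_by_clustering(matrix)
        groups = extract_groups(matrix, ordering, min_size=7)
        assert [g.size for g in groups] == [8, 9]
        assert all(g.kind == "diagonal" for g in groups)

    def test_subthreshold_similarity_yields_no_groups(self):
        matrix = _block_matrix([10, 10], 0.4, 0.4)
        ordering, _ = order_by_clustering(matrix)
        assert extract_groups(matrix, ordering) == []

    def test_small_blocks_fall_below_min_size(self):
        matrix = _block_matrix([5, 9], 1.0, 0.0)
        ordering, _ = order_by_clustering(matrix)
        groups = extract_groups(matrix, ordering, min_size=7)
        assert [g.size for g in groups] == [9]

    def test_threshold_out_of_range_rejected(self):
        matrix = _block_matrix([4], 1.0, 0.0)
        with pytest.raises(ValueError):
            extract_groups(matrix, np.arange(4), threshold=1.5)

    def test_permutation_stability(self, rng):
        matrix = _block_matrix([8, 7, 9], 0.9, 0.05)
        ordering, _ = order_by_clustering(matrix)
        base = extract_groups(matrix, ordering)
        perm = rng.permutation(matrix.n)
        shuffled = SimilarityMatrix(
            matrix.values[np.ix_(perm, perm)], [matrix.labels[i] for i in perm]
        )
        ordering2, _ = order_by_clustering(shuffled)
        relabeled = extract_groups(shuffled, ordering2)
        assert sorted((frozenset(g.members) for g in base), key=sorted) == sorted(
            (frozenset(g.members) for g in relabeled), key=sorted
        )

    def test_off_diagonal_pair_under_complete_linkage(self):
        """Two internally tight blocks, strongly similar on average but with
        one dissimilar pair, separate under complete linkage and surface as
        an off-diagonal group."""
        sizes = [8, 8]
        sim = np.full((16, 16), 0.9)
        sim[:8, :8] = 1.0
        sim[8:, 8:] = 1.0
        sim[0, 8] = sim[8, 0] = 0.3  # one bad pair keeps the blocks apart
        np.fill_diagonal(sim, 1.0)
        matrix = SimilarityMatrix(sim, [f"m{i}" for i in range(16)])
        ordering, _ = order_by_clustering(matrix, linkage="complete")
        groups = extract_groups(matrix, ordering, min_size=7, linkage="complete")
        kinds = {g.kind for g in groups}
        assert "off_diagonal" in kinds
        off = next(g for g in groups if g.kind == "off_diagonal")
        assert off.size == 16

    def test_average_linkage_cut_leaves_no_off_diagonal(self, rng):
        matrix = _block_matrix([8, 8, 8], 0.95, 0.1)
        ordering, _ = order_by_clustering(matrix)
        groups = extract_groups(matrix, ordering)
        assert all(g.kind == "diagonal" for g in groups)


class TestOccupancy:
    def test_reported_group_ratios(self):
        """Published occupancy arithmetic: 59/488 → 12.1%, 184/488 → 37.7%."""
        sizes = [59, 43, 7, 19, 23, 13, 9, 11]
        expected = [12.1, 8.8, 1.4, 3.9, 4.7, 2.7, 1.8, 2.3]
        groups = [
            MoleculeGroup(str(i), tuple(f"g{i}_{j}" for j in range(s)), "diagonal")
            for i, s in enumerate(sizes)
        ]
        table = occupancy_table(groups, total=488)
        assert list(table["ratio_pct"][:-1]) == expected
        grouped = table.iloc[-1]
        assert grouped["n"] == 184
        assert grouped["ratio_pct"] == 37.7

    def test_empty_group_list(self):
        table = occupancy_table([], total=100)
        assert list(table["n"]) == [0]
        assert list(table["ratio_pct"]) == [0.0]

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            occupancy_table([], total=0)
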