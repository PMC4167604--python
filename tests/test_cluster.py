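import numpy as np
import pytest

from edisom import (
    BMUMap,
    SOMGrid,
    build_grid,
    cluster_sizes,
    find_seeds,
    map_bmu,
    merge_closest_seeds,
    neighbor_distance,
    partition,
)
from edisom.preprocess import FoldChangeMatrix


def _grid_with_codebook(rings, codebook, trained=True):
    template = build_grid(np.zeros((2, np.shape(codebook)[1])), rings_override=rings)
    return SOMGrid(
        rings=rings,
        unit_coords=template.unit_coords,
        codebook=np.asarray(codebook, dtype=float),
        trained=trained,
    )


def _two_blob_grid():
    """r=3 grid split by Cartesian x: left blob ~ 0, right blob ~ 10, mid column between."""
    template = build_grid(np.zeros((2, 2)), rings_override=3)
    x = template.cartesian[:, 0]
    codebook = np.where(x[:, None] < -0.4, 0.0, np.where(x[:, None] > 0.4, 10.0, 5.0))
    codebook = np.broadcast_to(codebook, (template.n_units, 2)).copy()
    grid = SOMGrid(rings=3, unit_coords=template.unit_coords, codebook=codebook, trained=True)
    left = set(np.flatnonzero(x < -0.4))
    right = set(np.flatnonzero(x > 0.4))
    return grid, left, right


class TestNeighborDistance:
    def test_identical_codebooks_give_zero_heights(self):
        grid = _grid_with_codebook(3, np.ones((19, 4)))
        np.testing.assert_array_equal(neighbor_distance(grid), np.zeros(19))

    def test_single_unit_grid_height_zero(self):
        grid = _grid_with_codebook(1, [[2.0, 3.0]])
        np.testing.assert_array_equal(neighbor_distance(grid), [0.0])

    def test_matches_hand_computed_means_on_r2_grid(self):
        # unit order is (row, q) lexicographic; scalar codebooks 0..6 with a 7
        # at the last unit give hand-computable neighbor means over the ring
        # adjacency 0-1, 0-2, 1-4, 2-5, 4-6, 5-6 plus the center 3 <-> all.
        grid = _grid_with_codebook(2, [[0.0], [1.0], [2.0], [3.0], [4.0], [5.0], [7.0]])
        expected = [2.0, 2.0, 2.0, 13 / 6, 7 / 3, 7 / 3, 3.0]
        np.testing.assert_allclose(neighbor_distance(grid), expected)

    def test_untrained_grid_rejected(self):
        grid = _grid_with_codebook(2, np.zeros((7, 2)), trained=False)
        with pytest.raises(ValueError, match="trained"):
            neighbor_distance(grid)


class TestFindSeeds:
    def test_uniform_heights_collapse_to_unit_zero(self):
        grid = _grid_with_codebook(3, np.ones((19, 2)))
        assert find_seeds(grid, np.zeros(19)) == [0]

    def test_single_unit_grid_is_its_own_seed(self):
        grid = _grid_with_codebook(1, [[1.0]])
        assert find_seeds(grid, np.zeros(1)) == [0]

    def test_two_blobs_give_two_seeds_one_inside_each(self):
        grid, left, right = _two_blob_grid()
        heights = neighbor_distance(grid)
        # independent oracle: exhaustive local-minimum scan over the lattice
        nbrs = grid.neighbor_lists()
        minima = {
            u for u in range(grid.n_units)
            if all(heights[u] <= heights[v] for v in nbrs[u])
        }
        seeds = find_seeds(grid, heights)
        assert len(seeds) == 2
        assert set(seeds) <= minima
        assert len(set(seeds) & left) == 1 and len(set(seeds) & right) == 1

    def test_height_length_mismatch_errors(self):
        grid = _grid_with_codebook(2, np.zeros((7, 2)))
        with pytest.raises(ValueError, match="heights"):
            find_seeds(grid, np.zeros(6))


class TestPartition:
    @staticmethod
    def _bmu_for(grid, values, ids=None):
        ids = ids or tuple(f"g{i}" for i in range(len(values)))
        fc = FoldChangeMatrix(tuple(ids), tuple(f"s{j}" for j in range(grid.n_stages)),
                              np.asarray(values, dtype=float))
        return map_bmu(grid, fc)

    def test_single_seed_captures_everything(self):
        grid = _grid_with_codebook(2, np.arange(14).reshape(7, 2))
        bmu = self._bmu_for(grid, np.arange(14).reshape(7, 2))
        part = partition(grid, [3], bmu)
        assert part.n_clusters == 1
        assert np.all(part.unit_cluster == 1)
        assert set(part.gene_cluster.values()) == {1}

    def test_two_blob_units_join_their_own_seed(self):
        grid, left, right = _two_blob_grid()
        heights = neighbor_distance(grid)
        seeds = find_seeds(grid, heights)
        bmu = self._bmu_for(grid, [[0.0, 0.0], [10.0, 10.0]])
        part = partition(grid, seeds, bmu)
        left_cluster = part.unit_cluster[min(set(seeds) & left)]
        right_cluster = part.unit_cluster[min(set(seeds) & right)]
        assert all(part.unit_cluster[u] == left_cluster for u in left)
        assert all(part.unit_cluster[u] == right_cluster for u in right)
        assert part.gene_cluster["g0"] == left_cluster
        assert part.gene_cluster["g1"] == right_cluster

    def test_partition_covers_every_unit_exactly_once(self, small_trained):
        kept, grid, bmu = small_trained
        seeds = find_seeds(grid, neighbor_distance(grid))
        part = partition(grid, seeds, bmu)
        assert part.unit_cluster.shape == (grid.n_units,)
        assert np.all((part.unit_cluster >= 1) & (part.unit_cluster <= part.n_clusters))

    def test_seed_units_are_fixed_points(self, small_trained):
        _kept, grid, bmu = small_trained
        seeds = find_seeds(grid, neighbor_distance(grid))
        part = partition(grid, seeds, bmu)
        for k, u in part.seed_units.items():
            assert part.unit_cluster[u] == k
            np.testing.assert_array_equal(part.seed_profiles[k], grid.codebook[u])

    def test_genes_inherit_their_bmu_cluster(self, small_trained):
        _kept, grid, bmu = small_trained
        part = partition(grid, find_seeds(grid, neighbor_distance(grid)), bmu)
        for tid, unit in bmu.assignment.items():
            assert part.gene_cluster[tid] == part.unit_cluster[unit]

    def test_empty_seed_list_errors(self, small_trained):
        _kept, grid, bmu = small_trained
        with pytest.raises(ValueError, match="empty"):
            partition(grid, [], bmu)

    def test_repeated_partition_is_identical(self, small_trained):
        _kept, grid, bmu = small_trained
        seeds = find_seeds(grid, neighbor_distance(grid))
        a = partition(grid, seeds, bmu)
        b = partition(grid, seeds, bmu)
        np.testing.assert_array_equal(a.unit_cluster, b.unit_cluster)
        assert a.gene_cluster == b.gene_cluster


class TestClusterSizes:
    def test_all_genes_one_cluster(self):
        grid = _grid_with_codebook(1, [[0.0]])
        bmu = BMUMap({f"g{i}": 0 for i in range(10)}, 0.0)
        part = partition(grid, [0], bmu)
        assert cluster_sizes(part) == {1: 10}

    def test_sizes_sum_to_assigned_transcripts(self, small_trained):
        kept, grid, bmu = small_trained
        part = partition(grid, find_seeds(grid, neighbor_distance(grid)), bmu)
        assert sum(cluster_sizes(part).values()) == kept.n_transcripts


class TestMergeSeeds:
    def test_cap_merges_closest_codebooks(self):
        cb = np.array([[0.0, 0], [0.1, 0], [5.0, 0], [9.0, 0], [9.05, 0],
                       [3.0, 0], [7.0, 0]])
        grid = _grid_with_codebook(2, cb)
        merged = merge_closest_seeds(grid, [0, 1, 3, 4], max_clusters=2)
        # pairs (0,1) at 0.1 and (3,4) at 0.05 collapse to their lower indices
        assert merged == [0, 3]

    def test_cap_not_binding_is_identity(self):
        grid = _grid_with_codebook(2, np.arange(14).reshape(7, 2))
        assert merge_closest_seeds(grid, [1, 5], max_clusters=4) == [1, 5]
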