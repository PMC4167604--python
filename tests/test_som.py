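import math

import numpy as np
import pytest

from edisom import (
    FoldChangeMatrix,
    SOMGrid,
    TrainingPhase,
    TrainingSchedule,
    build_grid,
    choose_rings,
    default_schedule,
    hex_distance,
    map_bmu,
    quantization_error,
    train,
)


def _fc(values):
    values = np.asarray(values, dtype=float)
    return FoldChangeMatrix(
        transcript_ids=tuple(f"t{i}" for i in range(values.shape[0])),
        stage_labels=tuple(f"s{j}" for j in range(values.shape[1])),
        values=values,
    )


def _scan_rings_oracle(n):
    # independent brute-force scan of the sizing objective
    gaps = [(abs(3 * r * (r - 1) + 1 - 5 * math.sqrt(n)), r) for r in range(1, 51)]
    return min(gaps)[1]


class TestGridGeometry:
    @pytest.mark.parametrize("n,expected_rings,expected_units",
                             [(1893, 9, 217), (4, 2, 7)])
    def test_sizing_heuristic(self, n, expected_rings, expected_units):
        r = choose_rings(n)
        assert r == expected_rings == _scan_rings_oracle(n)
        grid = build_grid(np.zeros((2, 2)), rings_override=r)
        assert grid.n_units == expected_units

    @pytest.mark.parametrize("n", [1, 3, 17, 50, 333, 5000, 120000])
    def test_sizing_matches_scan_oracle(self, n):
        assert choose_rings(n) == _scan_rings_oracle(n)

    def test_rings_override_one_gives_single_unit(self):
        grid = build_grid(np.zeros((3, 2)), rings_override=1)
        assert grid.n_units == 1

    def test_rings_override_below_one_errors(self):
        with pytest.raises(ValueError, match="rings_override"):
            build_grid(np.zeros((3, 2)), rings_override=0)

    def test_unit_count_formula(self):
        for r in range(1, 8):
            grid = build_grid(np.zeros((2, 2)), rings_override=r)
            assert grid.n_units == 3 * r * (r - 1) + 1

    def test_hex_distance_identity_and_adjacency(self):
        grid = build_grid(np.zeros((2, 2)), rings_override=3)
        assert hex_distance(4, 4, grid) == 0.0
        # axial (0,0) and (1,0) are adjacent; (1,1) sits sqrt(3) away
        coords = {tuple(c): i for i, c in enumerate(grid.unit_coords)}
        origin, right, diag = coords[(0, 0)], coords[(1, 0)], coords[(1, 1)]
        assert hex_distance(origin, right, grid) == pytest.approx(1.0)
        assert hex_distance(origin, diag, grid) == pytest.approx(math.sqrt(3))

    def test_hex_distance_invalid_index_errors(self):
        grid = build_grid(np.zeros((2, 2)), rings_override=2)
        with pytest.raises(IndexError):
            hex_distance(0, 7, grid)

    def test_hex_distance_symmetry_and_triangle_inequality_exhaustive(self):
        grid = build_grid(np.zeros((2, 2)), rings_override=4)
        n = grid.n_units
        d = np.array([[hex_distance(u, v, grid) for v in range(n)] for u in range(n)])
        np.testing.assert_allclose(d, d.T)
        for u in range(n):
            for v in range(n):
                assert np.all(d[u, v] <= d[u] + d[:, v] + 1e-9)

    def test_every_interior_unit_has_six_neighbors(self):
        grid = build_grid(np.zeros((2, 2)), rings_override=3)
        counts = [len(nbrs) for nbrs in grid.neighbor_lists()]
        assert max(counts) == 6
        assert sorted(counts)[:6] == [3] * 6  # the six corners of the hexagon


class TestInitialization:
    def test_principal_plane_init_is_deterministic_and_spans_data(self, rng):
        X = rng.normal(0, 1, size=(50, 4)) @ np.diag([3.0, 1.5, 0.2, 0.1])
        a = build_grid(X, rings_override=3, seed=0)
        b = build_grid(X, rings_override=3, seed=99)  # seed unused on full-rank data
        np.testing.assert_array_equal(a.codebook, b.codebook)
        assert a.codebook.std() > 0

    def test_rank_deficient_data_falls_back_to_seeded_random(self):
        X = np.tile([1.0, 2.0, 3.0], (10, 1))  # zero variance: rank 0
        a = build_grid(X, rings_override=2, seed=5)
        b = build_grid(X, rings_override=2, seed=5)
        c = build_grid(X, rings_override=2, seed=6)
        np.testing.assert_array_equal(a.codebook, b.codebook)
        assert not np.array_equal(a.codebook, c.codebook)


class TestTraining:
    def test_constant_input_is_fixed_point(self):
        v = np.array([0.7, -1.1, 0.3])
        fc = _fc(np.tile(v, (12, 1)))
        grid = train(build_grid(fc, rings_override=3), fc)
        assert np.max(np.abs(grid.codebook - v)) < 1e-6

    def test_single_sequential_bmu_update(self):
        # one unit, one sample, alpha = 0.5: m' = m + alpha (x - m) = 0.5
        grid = SOMGrid(
            rings=1, unit_coords=np.array([[0, 0]]), codebook=np.array([[0.0]])
        )
        schedule = TrainingSchedule(
            phases=(TrainingPhase(1, sigma_start=1e-6, sigma_end=1e-6,
                                  rate_start=0.5, rate_end=0.5),),
            mode="sequential",
        )
        trained = train(grid, np.array([[1.0]]), schedule)
        assert trained.codebook[0, 0] == pytest.approx(0.5)

    def test_training_reduces_quantization_error(self, small_dataset):
        from edisom import apply_floor, fold_change, regulation_filter

        _spec, matrix, _truth = small_dataset
        kept, _ = regulation_filter(fold_change(apply_floor(matrix)))
        grid0 = build_grid(kept)
        qe0 = quantization_error(grid0, kept)
        qe1 = quantization_error(train(grid0, kept), kept)
        assert qe1 <= qe0

    def test_batch_training_is_seed_independent_and_reproducible(self, rng):
        fc = _fc(rng.normal(0, 1, size=(30, 4)))
        grid = build_grid(fc, rings_override=3)
        a = train(grid, fc, default_schedule(grid, 30, seed=1))
        b = train(grid, fc, default_schedule(grid, 30, seed=2))
        np.testing.assert_array_equal(a.codebook, b.codebook)

    def test_sequential_training_is_seed_reproducible(self, rng):
        fc = _fc(rng.normal(0, 1, size=(30, 4)))
        grid = build_grid(fc, rings_override=3)
        a = train(grid, fc, default_schedule(grid, 30, mode="sequential", seed=3))
        b = train(grid, fc, default_schedule(grid, 30, mode="sequential", seed=3))
        np.testing.assert_array_equal(a.codebook, b.codebook)

    def test_narrow_kernel_batch_epochs_never_increase_quantization_error(self, rng):
        # sigma below the unit spacing: batch SOM behaves like k-means Lloyd steps
        fc = _fc(rng.normal(0, 1, size=(40, 3)))
        grid = build_grid(fc, rings_override=3)
        schedule = TrainingSchedule(
            phases=(TrainingPhase(1, sigma_start=0.2, sigma_end=0.2),), mode="batch"
        )
        current = train(grid, fc, schedule)
        qe = quantization_error(current, fc)
        for _ in range(5):
            current = train(current, fc, schedule, allow_retrain=True)
            qe_next = quantization_error(current, fc)
            assert qe_next <= qe + 1e-12
            qe = qe_next

    def test_retraining_requires_explicit_flag(self, rng):
        fc = _fc(rng.normal(size=(10, 3)))
        grid = train(build_grid(fc, rings_override=2), fc)
        with pytest.raises(ValueError, match="already trained"):
            train(grid, fc)

    def test_stage_count_mismatch_errors(self, rng):
        fc = _fc(rng.normal(size=(10, 3)))
        grid = build_grid(fc, rings_override=2)
        with pytest.raises(ValueError, match="codebook width"):
            train(grid, _fc(np.zeros((5, 4))))


class TestBMU:
    def test_exact_codebook_match_wins(self, rng):
        fc = _fc(rng.normal(size=(6, 3)))
        grid = train(build_grid(fc, rings_override=2), fc)
        target_unit = 4
        probe = FoldChangeMatrix(("probe",), fc.stage_labels,
                                 grid.codebook[[target_unit]])
        assert map_bmu(grid, probe).assignment["probe"] == target_unit

    def test_tie_breaks_to_lowest_unit_index(self):
        codebook = np.zeros((7, 3))  # all units identical: every unit ties
        grid = SOMGrid(
            rings=2,
            unit_coords=build_grid(np.zeros((2, 3)), rings_override=2).unit_coords,
            codebook=codebook,
            trained=True,
        )
        bmu = map_bmu(grid, _fc([[5.0, 5.0, 5.0]]))
        assert bmu.assignment["t0"] == 0

    def test_matches_exhaustive_nearest_unit_scan(self, rng):
        fc = _fc(rng.normal(0, 2, size=(20, 4)))
        grid = train(build_grid(fc, rings_override=5), fc)  # 61 units
        bmu = map_bmu(grid, fc)
        for i, tid in enumerate(fc.transcript_ids):
            # brute-force oracle: explicit loop over all units
            best_unit, best_dist = None, np.inf
            for u in range(grid.n_units):
                d = float(np.sqrt(np.sum((fc.values[i] - grid.codebook[u]) ** 2)))
                if d < best_dist:
                    best_unit, best_dist = u, d
            assert bmu.assignment[tid] == best_unit

    def test_untrained_grid_rejected(self, rng):
        fc = _fc(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="trained"):
            map_bmu(build_grid(fc, rings_override=2), fc)

    def test_quantization_error_definition(self, rng):
        fc = _fc(rng.normal(size=(15, 3)))
        grid = train(build_grid(fc, rings_override=3), fc)
        bmu = map_bmu(grid, fc)
        expected = np.mean(
            [
                np.linalg.norm(fc.values[i] - grid.codebook[bmu.assignment[tid]])
                for i, tid in enumerate(fc.transcript_ids)
            ]
        )
        assert bmu.quantization_error == pytest.approx(expected)
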