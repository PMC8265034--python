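import numpy as np
import pytest

from mrflesion.dictionary import (
    Dictionary,
    ParameterGrid,
    build_dictionary,
    build_grid,
    default_grid,
    load_dictionary,
    match_fingerprints,
    match_voxel,
    reconstruct_maps,
    save_dictionary,
)
from mrflesion.signal import BaselineStack, simulate_fingerprint, simulate_magnitude



class TestBuildGrid:
    def test_starts_at_minimum(self):
        assert build_grid(300.0, 3500.0, 0.05)[0] == 300.0

    def test_exact_relative_spacing(self):
        grid = build_grid(300.0, 3500.0, 0.05)
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, 1.05, rtol=1e-12)

    def test_covers_maximum_within_one_step(self):
        for vmin, vmax in ((300.0, 3500.0), (10.0, 2500.0)):
            grid = build_grid(vmin, vmax, 0.05)
            assert grid[-1] >= vmax
            assert grid[-2] < vmax
            assert grid[-1] < vmax * 1.05

    def test_short_grid_brute_force(self):
        # enumerate 10 * 1.05^k: 10, 10.5 — 10 < 10.4 so one more entry covers
        assert list(build_grid(10.0, 10.4, 0.05)) == [10.0, pytest.approx(10.5)]

    def test_exact_endpoint_not_overshot(self):
        grid = build_grid(10.0, 10.0 * 1.05**3, 0.05)
        assert grid.size == 4
        assert grid[-1] == pytest.approx(10.0 * 1.05**3)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            build_grid(100.0, 100.0, 0.05)
        with pytest.raises(ValueError):
            build_grid(-1.0, 10.0, 0.05)


class TestDefaultGrid:
    def test_b1_arithmetic_nine_entries(self):
        grid = default_grid()
        np.testing.assert_allclose(grid.b1_values, np.arange(0.6, 1.45, 0.1), atol=1e-9)
        assert grid.b1_values.size == 9

    def test_ranges(self):
        grid = default_grid()
        assert grid.t1_values[0] == 300.0
        assert grid.t2s_values[0] == 10.0
        assert grid.t1_values[-1] >= 3500.0
        assert grid.t2s_values[-1] >= 2500.0


class TestBuildDictionary:
    def test_atom_count_is_grid_product(self, schedule):
        grid = ParameterGrid(
            t1_values=np.array([400.0, 800.0, 1600.0]),
            t2s_values=np.array([30.0, 60.0]),
            b1_values=np.array([1.0]),
        )
        d = build_dictionary(schedule, grid)
        assert d.n_atoms == 6

    def test_unit_norms(self, coarse_dictionary):
        norms = np.linalg.norm(coarse_dictionary.atoms, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_index_round_trips_to_grid(self, coarse_dictionary):
        g = coarse_dictionary.grid
        assert set(np.unique(coarse_dictionary.index[:, 0])) == set(g.t1_values)
        assert set(np.unique(coarse_dictionary.index[:, 2])) == set(g.b1_values)

    def test_persistence_round_trip(self, tmp_path, coarse_dictionary):
        path = tmp_path / "dict.npz"
        save_dictionary(coarse_dictionary, path)
        loaded = load_dictionary(path)
        np.testing.assert_array_equal(loaded.atoms, coarse_dictionary.atoms)
        np.testing.assert_array_equal(loaded.index, coarse_dictionary.index)
        assert loaded.schedule == coarse_dictionary.schedule


class TestMatchVoxel:
    def test_atom_identity(self, coarse_dictionary, schedule):
        t1, t2s, b1 = coarse_dictionary.index[1234]
        fp = simulate_fingerprint(t1, t2s, 1.0, b1, schedule)
        mt1, mt2s, mb1, m0, corr = match_voxel(fp, coarse_dictionary)
        assert (mt1, mt2s, mb1) == (t1, t2s, b1)
        assert corr == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, coarse_dictionary, schedule):
        t1, t2s, b1 = coarse_dictionary.index[1234]
        fp = simulate_fingerprint(t1, t2s, 1.0, b1, schedule)
        r1 = match_voxel(fp, coarse_dictionary)
        r2 = match_voxel(7.3 * fp, coarse_dictionary)
        assert r1[:3] == r2[:3]
        assert r2[3] == pytest.approx(7.3 * r1[3], rel=1e-9)

    def test_all_zero_fingerprint_flagged_background(self, coarse_dictionary):
        result = match_voxel(np.zeros(coarse_dictionary.n_frames), coarse_dictionary)
        assert result == (0.0, 0.0, 0.0, 0.0, 0.0)

    def test_wrong_length_rejected(self, coarse_dictionary):
        with pytest.raises(ValueError, match="frames"):
            match_voxel(np.ones(12), coarse_dictionary)

    def test_off_grid_precision_five_percent(self, default_dictionary, schedule):
        # noiseless off-grid draws at unit B1 match within the 5% grid step
        rng = np.random.default_rng(42)
        n = 200
        t1 = np.exp(rng.uniform(np.log(300.0), np.log(3500.0), n))
        t2s = np.exp(rng.uniform(np.log(10.0), np.log(2500.0), n))
        fp = simulate_magnitude(t1, t2s, 1.0, 1.0, schedule)
        res = match_fingerprints(fp, default_dictionary)
        assert np.max(np.abs(res.t1_ms - t1) / t1) <= 0.05
        assert np.max(np.abs(res.t2s_ms - t2s) / t2s) <= 0.05

    def test_chunked_matching_equals_brute_force(self, coarse_dictionary, schedule):
        rng = np.random.default_rng(3)
        n = 100
        t1 = np.exp(rng.uniform(np.log(300.0), np.log(3500.0), n))
        t2s = np.exp(rng.uniform(np.log(10.0), np.log(2500.0), n))
        b1 = rng.uniform(0.8, 1.2, n)
        fp = simulate_magnitude(t1, t2s, 1.0, b1, schedule)
        fast = match_fingerprints(fp, coarse_dictionary, chunk=7)
        # naive exhaustive oracle, one fingerprint at a time
        atoms = coarse_dictionary.atoms
        for i in range(n):
            v = fp[i] / np.linalg.norm(fp[i])
            best = int(np.argmax(atoms @ v))
            assert fast.t1_ms[i] == coarse_dictionary.index[best, 0]
            assert fast.t2s_ms[i] == coarse_dictionary.index[best, 1]
            assert fast.b1_scale[i] == coarse_dictionary.index[best, 2]


class TestReconstructMaps:
    def _on_grid_stack(self, dictionary, schedule):
        # small volume whose voxel values all lie exactly on the grid
        g = dictionary.grid
        rng = np.random.default_rng(0)
        shape = (8, 8, 2)
        t1 = rng.choice(g.t1_values, size=shape)
        t2s = rng.choice(g.t2s_values, size=shape)
        b1 = rng.choice(g.b1_values, size=shape)
        data = simulate_magnitude(t1, t2s, 1.0, b1, schedule).astype(np.float32)
        stack = BaselineStack(data, (1, 1, 2), schedule)
        return stack, t1, t2s, b1

    def test_on_grid_identity(self, coarse_dictionary, schedule):
        stack, t1, t2s, b1 = self._on_grid_stack(coarse_dictionary, schedule)
        mask = np.ones(stack.shape, dtype=bool)
        qm = reconstruct_maps(stack, coarse_dictionary, mask)
        np.testing.assert_array_equal(qm.t1_ms, t1)
        np.testing.assert_array_equal(qm.t2s_ms, t2s)
        np.testing.assert_array_equal(qm.b1_scale, b1)

    def test_empty_mask_gives_zero_maps(self, coarse_dictionary, schedule):
        stack, *_ = self._on_grid_stack(coarse_dictionary, schedule)
        qm = reconstruct_maps(stack, coarse_dictionary, np.zeros(stack.shape, bool))
        assert np.all(qm.t1_ms == 0)
        assert np.all(qm.correlation == 0)

    def test_outside_mask_zero(self, coarse_dictionary, schedule):
        stack, *_ = self._on_grid_stack(coarse_dictionary, schedule)
        mask = np.zeros(stack.shape, dtype=bool)
        mask[:4] = True
        qm = reconstruct_maps(stack, coarse_dictionary, mask)
        assert np.all(qm.t1_ms[~mask] == 0)
        assert np.all(qm.t1_ms[mask] > 0)

    def test_frame_mismatch_rejected(self, coarse_dictionary, schedule):
        from mrflesion.schedule import FingerprintSchedule

        short = FingerprintSchedule(
            schedule.flip_deg[:10], schedule.te_ms[:10], schedule.tr_ms[:10],
            ti_ms=schedule.ti_ms[:10],
        )
        stack = BaselineStack(np.ones((4, 4, 1, 10), np.float32), (1, 1, 2), short)
        with pytest.raises(ValueError, match="frames"):
            reconstruct_maps(stack, coarse_dictionary, np.ones((4, 4, 1), bool))

    def test_error_shrinks_with_finer_grid(self, schedule):
        rng = np.random.default_rng(5)
        n = 100
        t1 = np.exp(rng.uniform(np.log(400.0), np.log(3000.0), n))
        t2s = np.exp(rng.uniform(np.log(20.0), np.log(2000.0), n))
        fp = simulate_magnitude(t1, t2s, 1.0, 1.0, schedule)
        errs = []
        for step in (0.10, 0.05):
            grid = ParameterGrid(
                t1_values=build_grid(300.0, 3500.0, step),
                t2s_values=build_grid(10.0, 2500.0, step),
                b1_values=np.array([1.0]),
            )
            d = build_dictionary(schedule, grid)
            res = match_fingerprints(fp, d)
            errs.append(np.mean(np.abs(res.t1_ms - t1) / t1)
                        + np.mean(np.abs(res.t2s_ms - t2s) / t2s))
        assert errs[1] < errs[0]
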