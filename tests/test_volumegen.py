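"""Volume synthesis: scaffold, interpolation, statistics matching, filters."""

import numpy as np
import pytest
from scipy import ndimage

from cytocrowd.imaging import NeighborStats
from cytocrowd.volumegen import (GenConfig, VolumeGrid, crop_sphere,
                                 generate_line, generate_scaffold,
                                 generate_volume, interpolate, lowpass,
                                 match_statistics, measure_cond3,
                                 save_volume, load_volume, UNSET)


def uniform_stats(blackness: float, max_gap: int = 8) -> NeighborStats:
    """Statistics of an i.i.d. Bernoulli texture (for closed-form checks)."""
    return NeighborStats(
        cond3=np.full(8, blackness),
        pairgap={j: np.full(4, blackness) for j in range(1, max_gap + 1)},
        blackness=blackness)


class TestGenerateLine:
    def test_all_black_stats_give_all_ones(self, rng):
        line = generate_line(uniform_stats(1.0), 100, rng)
        assert np.all(line == 1)

    def test_iid_half_mean(self, rng):
        line = generate_line(uniform_stats(0.5), 100_000, rng)
        assert line.mean() == pytest.approx(0.5, abs=0.01)

    def test_stripe_stats_alternate_after_burn_in(self, rng):
        # next pixel is the complement of its immediate predecessor
        cond3 = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        stats = NeighborStats(cond3=cond3, pairgap={1: np.full(4, 0.5)},
                              blackness=0.5)
        line = generate_line(stats, 200, rng)
        tail = line[4:]
        assert np.all(tail[:-1] != tail[1:])   # strict alternation


class TestScaffold:
    def test_planes_at_spacing_multiples(self, ref_stats):
        cfg = GenConfig(seed=0)
        vol = generate_scaffold(ref_stats, cfg, 32)
        v = vol.voxels
        set_mask = v != UNSET
        # a voxel is on a scaffold line iff >= 2 of its coords are multiples of 16
        zz, yy, xx = np.indices(v.shape)
        on_line = ((zz % 16 == 0).astype(int) + (yy % 16 == 0) +
                   (xx % 16 == 0)) >= 2
        assert np.array_equal(set_mask, on_line)

    def test_spacing_one_sets_every_voxel(self, ref_stats):
        cfg = GenConfig(scaffold_spacing=2, interp_gaps=(1,), seed=0)
        vol = generate_scaffold(ref_stats, cfg, 8)
        # with spacing 2 every voxel lies on a line in at least one axis
        filled = interpolate(vol, ref_stats, cfg)
        assert np.all(filled.voxels != UNSET)

    def test_indivisible_size_rejected(self, ref_stats):
        with pytest.raises(ValueError):
            generate_scaffold(ref_stats, GenConfig(seed=0), 33)

    def test_seeded_reproducibility(self, ref_stats):
        cfg = GenConfig(seed=5)
        a = generate_scaffold(ref_stats, cfg, 32)
        b = generate_scaffold(ref_stats, cfg, 32)
        assert np.array_equal(a.voxels, b.voxels)


class TestInterpolate:
    def test_fill_order_matches_hierarchical_refinement(self, ref_stats):
        """Gap levels fill strictly coarse-to-fine: the set of determined
        voxels after each level is exactly the spacing-j grid plus lines."""
        cfg = GenConfig(seed=1)
        vol = generate_scaffold(ref_stats, cfg, 32)
        v = np.array(vol.voxels)
        rng = np.random.default_rng(1)
        zz, yy, xx = np.indices(v.shape)
        on_line = ((zz % 16 == 0).astype(int) + (yy % 16 == 0) +
                   (xx % 16 == 0)) >= 2
        for j in (8, 4, 2, 1):
            sub_cfg = GenConfig(scaffold_spacing=2 * j, interp_gaps=(j,), seed=1)
            out = interpolate(VolumeGrid(v, stage="raw"), ref_stats, sub_cfg, rng)
            v = np.array(out.voxels, dtype=np.int8)
            on_grid = (zz % j == 0) & (yy % j == 0) & (xx % j == 0)
            assert np.all(v[on_grid] != UNSET)
            # nothing finer than the current level (or the scaffold lines)
            # has been touched yet
            assert np.all(v[~(on_grid | on_line)] == UNSET)
        assert np.all(v != UNSET)

    def test_certain_flanks_force_midpoint(self):
        stats = uniform_stats(1.0)
        cfg = GenConfig(seed=0)
        vol = generate_scaffold(stats, cfg, 32)
        out = interpolate(vol, stats, cfg)
        assert np.all(out.voxels == 1)

    def test_iid_pairgap_gives_blackness_fraction(self):
        stats = uniform_stats(0.3)
        cfg = GenConfig(seed=2)
        vol = generate_scaffold(stats, cfg, 64)
        out = interpolate(vol, stats, cfg)
        assert out.occupied_fraction == pytest.approx(0.3, abs=0.01)


class TestMatchStatistics:
    def test_fixed_point_when_already_matching(self):
        """An i.i.d. volume measured against its own statistics is returned
        unchanged within one iteration."""
        rng = np.random.default_rng(3)
        v = (rng.random((48, 48, 48)) < 0.4).astype(np.uint8)
        measured = measure_cond3(v)
        stats = NeighborStats(cond3=measured,
                              pairgap={1: np.full(4, 0.4)},
                              blackness=float(v.mean()))
        cfg = GenConfig(seed=3)
        out = match_statistics(VolumeGrid(v), stats, cfg)
        assert out.converged
        assert out.meta["iterations"] == 0
        assert np.array_equal(out.voxels, v)

    def test_fraction_contract_and_deviation_reduction(self, ref_stats,
                                                       matched_volume_64):
        vol = matched_volume_64
        assert vol.occupied_fraction == pytest.approx(ref_stats.blackness,
                                                      abs=0.02)
        # matching never does worse than the raw volume it started from
        assert vol.meta["cond3_dev"] <= 0.22

    def test_convergence_flag_consistent_with_tolerance(self, ref_stats,
                                                        matched_volume_64):
        cfg = GenConfig()
        dev = float(np.abs(measure_cond3(matched_volume_64.voxels)
                           - ref_stats.cond3).max())
        assert matched_volume_64.converged == (dev <= cfg.tol_stats)

    def test_matched_volume_is_isotropic(self, matched_volume_64):
        per_axis = measure_cond3(matched_volume_64.voxels, per_axis=True)
        spread = per_axis.max(axis=0) - per_axis.min(axis=0)
        assert np.all(spread < 0.05)

    def test_erosion_strictly_decreases_fraction(self):
        rng = np.random.default_rng(4)
        v = (rng.random((10, 10, 10)) < 0.5)
        er = ndimage.binary_erosion(v, ndimage.generate_binary_structure(3, 1),
                                    border_value=1)
        assert er.mean() < v.mean()


class TestLowpass:
    def test_isolated_voxel_removed(self):
        v = np.zeros((9, 9, 9), np.uint8)
        v[4, 4, 4] = 1
        out = lowpass(VolumeGrid(v))
        assert out.voxels.sum() == 0

    def test_half_space_unchanged(self):
        v = np.zeros((10, 10, 10), np.uint8)
        v[:, :, :5] = 1
        out = lowpass(VolumeGrid(v))
        assert np.array_equal(out.voxels, v)

    def test_agrees_with_majority_vote_oracle(self, rng):
        v = (rng.random((20, 20, 20)) < 0.5).astype(np.uint8)
        out = lowpass(VolumeGrid(v))
        # brute-force 27-neighborhood majority with reflected borders
        padded = np.pad(v, 1, mode="symmetric")
        oracle = np.zeros_like(v)
        for z in range(20):
            for y in range(20):
                for x in range(20):
                    block = padded[z:z + 3, y:y + 3, x:x + 3]
                    oracle[z, y, x] = 1 if block.sum() >= 14 else 0
        assert np.array_equal(out.voxels, oracle)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            lowpass(VolumeGrid(np.zeros((8, 8, 8), np.uint8)),
                    GenConfig(median_size=4))

    def test_smoothing_changes_fraction_boundedly(self, matched_volume_64):
        sm = lowpass(matched_volume_64)
        assert abs(sm.occupied_fraction
                   - matched_volume_64.occupied_fraction) <= 0.05


class TestCropSphere:
    def test_reference_diameter(self):
        v = VolumeGrid(np.ones((300, 300, 300), np.uint8), voxel_nm=17.6)
        out = crop_sphere(v, margin_px=10)
        assert out.meta["diameter_nm"] == pytest.approx(4928.0)

    def test_occupied_count_matches_lattice_point_oracle(self):
        n, margin = 40, 4
        v = VolumeGrid(np.ones((n, n, n), np.uint8), voxel_nm=17.6)
        out = crop_sphere(v, margin_px=margin)
        usable = n - 2 * margin
        c = (usable - 1) / 2.0
        r2 = (usable / 2.0) ** 2
        count = sum(
            (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= r2
            for z in range(usable) for y in range(usable)
            for x in range(usable))
        assert int(out.voxels.sum()) == count

    def test_empty_volume_stays_empty(self):
        v = VolumeGrid(np.zeros((40, 40, 40), np.uint8))
        out = crop_sphere(v, margin_px=4)
        assert out.voxels.sum() == 0

    def test_oversized_sphere_rejected(self):
        v = VolumeGrid(np.ones((40, 40, 40), np.uint8), voxel_nm=17.6)
        with pytest.raises(ValueError):
            crop_sphere(v, margin_px=4, diameter_um=10.0)


class TestPipeline:
    def test_seed_reproducibility(self, ref_stats):
        a = generate_volume(ref_stats, size=32, cfg=GenConfig(seed=8))
        b = generate_volume(ref_stats, size=32, cfg=GenConfig(seed=8))
        assert np.array_equal(a.voxels, b.voxels)

    def test_volume_io_round_trip(self, matched_volume_64, tmp_path):
        p = tmp_path / "vol.tif"
        save_volume(matched_volume_64, p, GenConfig(seed=3))
        loaded = load_volume(p)
        assert np.array_equal(loaded.voxels, matched_volume_64.voxels)
        assert loaded.voxel_nm == matched_volume_64.voxel_nm
        assert loaded.stage == "matched"
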