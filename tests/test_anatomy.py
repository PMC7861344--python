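"""Phantom generation, grids, and preprocessing."""

import numpy as np
import pytest

from fluenceforge.anatomy import (
    Grid3D,
    PhantomConfig,
    StructureMask,
    build_fd_samples,
    crop_to_window,
    expand_structure,
    generate_phantom,
    normalize_dose,
    resample_volume,
    roi_slice_count,
)

COARSE = PhantomConfig.coarse()


class TestGeneratePhantom:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_invariants(self, seed):
        case = generate_phantom(seed, COARSE)
        lo, hi = COARSE.ptv_volume_cc
        assert lo * 0.8 <= case.ptv.volume_cc <= hi * 1.05
        assert case.oar.voxels.any()
        # the OAR approaches within the maximum sampled gap of the PTV
        expansion = expand_structure(case.ptv, COARSE.oar_gap_mm[1])
        assert (case.oar.voxels & expansion.voxels).any()
        # isocenter is the PTV centroid snapped to a voxel center
        centroid_idx = case.grid.physical_to_index(case.ptv.centroid())
        iso_idx = case.grid.physical_to_index(case.isocenter)
        assert np.allclose(iso_idx, np.rint(iso_idx))  # on a voxel center
        assert np.all(np.abs(iso_idx - centroid_idx) <= 0.5 + 1e-9)

    def test_deterministic(self):
        a = generate_phantom(1, COARSE)
        b = generate_phantom(1, COARSE)
        assert np.array_equal(a.density, b.density)
        assert np.array_equal(a.ptv.voxels, b.ptv.voxels)
        assert np.array_equal(a.oar.voxels, b.oar.voxels)
        assert np.array_equal(a.isocenter, b.isocenter)

    def test_volume_distribution_matches_config(self):
        # Monte-Carlo: empirical mean PTV volume within 20% of the
        # configured truncated-lognormal mean
        vols = [generate_phantom(s, COARSE).ptv.volume_cc for s in range(1, 61)]
        assert abs(np.mean(vols) - COARSE.mean_ptv_cc) <= 0.2 * COARSE.mean_ptv_cc


class TestResample:
    src = Grid3D(8, 8, 4, 2.0, 2.0, 2.0, (0.0, 0.0, 0.0))

    def test_constant_field(self):
        tgt = Grid3D(5, 5, 3, 1.5, 1.5, 1.5, (1.0, 1.0, 1.0))
        out = resample_volume(np.ones(self.src.shape), self.src, tgt, "linear")
        assert np.allclose(out, 1.0)

    def test_linear_ramp_midpoints(self):
        # 2 mm-spaced ramp resampled at 1 mm: midpoints average their neighbors
        vol = np.broadcast_to(
            np.arange(8, dtype=float)[:, None, None], self.src.shape
        ).copy()
        tgt = Grid3D(15, 8, 4, 1.0, 2.0, 2.0, (0.0, 0.0, 0.0))
        out = resample_volume(vol, self.src, tgt, "linear")
        expected = np.arange(15) * 0.5
        assert np.allclose(out[:, 0, 0], expected)

    def test_nearest_preserves_binary(self):
        rng = np.random.default_rng(0)
        mask = (rng.random(self.src.shape) > 0.5).astype(float)
        tgt = Grid3D(11, 11, 5, 1.3, 1.3, 1.3, (0.5, 0.5, 0.5))
        out = resample_volume(mask, self.src, tgt, "nearest")
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_disjoint_grids_error(self):
        tgt = Grid3D(4, 4, 2, 1.0, 1.0, 1.0, (1000.0, 1000.0, 1000.0))
        with pytest.raises(ValueError, match="overlap"):
            resample_volume(np.ones(self.src.shape), self.src, tgt)

    def test_unknown_mode_error(self):
        with pytest.raises(ValueError, match="mode"):
            resample_volume(np.ones(self.src.shape), self.src, self.src, "cubic")


class TestCrop:
    def test_centered_crop_is_subimage(self):
        grid = Grid3D(64, 64, 4, 1.0, 1.0, 2.0)
        vol = np.random.default_rng(0).random(grid.shape)
        iso = grid.index_to_physical([32, 32, 2])
        out, out_grid = crop_to_window(vol, grid, iso, window=32)
        assert np.array_equal(out, vol[16:48, 16:48, :])
        # window center index maps back to the isocenter
        assert np.allclose(out_grid.index_to_physical([16, 16, 2]), iso)

    def test_edge_padding(self):
        grid = Grid3D(64, 64, 4, 1.0, 1.0, 2.0)
        vol = np.ones(grid.shape)
        iso = grid.index_to_physical([10, 32, 2])
        out, _ = crop_to_window(vol, grid, iso, window=32)
        assert np.all(out[:6, :, :] == 0)       # zero-padded band
        assert np.all(out[6:, :, :] == 1)

    def test_idempotent(self):
        grid = Grid3D(48, 48, 4, 1.0, 1.0, 2.0)
        vol = np.random.default_rng(1).random(grid.shape)
        iso = grid.index_to_physical([24, 24, 1])
        once, g1 = crop_to_window(vol, grid, iso, window=32)
        twice, g2 = crop_to_window(once, g1, iso, window=32)
        assert np.array_equal(once, twice)
        assert g1 == g2

    def test_roundtrip_point_mapping(self):
        grid = Grid3D(64, 64, 8, 1.0, 1.0, 2.0, (-10.0, 5.0, 0.0))
        iso = grid.index_to_physical([20, 40, 3])
        _, win_grid = crop_to_window(np.zeros(grid.shape), grid, iso, window=32)
        point = grid.index_to_physical([22, 38, 3])
        idx = win_grid.physical_to_index(point)
        back = win_grid.index_to_physical(np.rint(idx))
        assert np.all(np.abs(back - point) <= 0.5 * grid.spacing + 1e-9)

    def test_outside_isocenter_error(self):
        grid = Grid3D(16, 16, 4)
        with pytest.raises(ValueError, match="isocenter"):
            crop_to_window(np.zeros(grid.shape), grid, np.array([1e4, 0, 0]))


class TestNormalizeDose:
    def test_values(self):
        assert normalize_dose(np.array(33.0)) == pytest.approx(100.0, rel=1e-12)
        assert normalize_dose(np.array(25.0)) == pytest.approx(25 / 33 * 100, rel=1e-12)
        assert normalize_dose(np.array(0.0)) == 0.0

    def test_negative_error(self):
        with pytest.raises(ValueError, match="negative"):
            normalize_dose(np.array([-1.0]))

    def test_invertible(self):
        d = np.array([0.0, 10.0, 33.0, 50.0])
        assert np.allclose(normalize_dose(d) / 100 * 33.0, d)


class TestExpandStructure:
    def test_zero_margin_identity(self):
        grid = Grid3D(10, 10, 5)
        mask = StructureMask(grid, np.zeros(grid.shape, dtype=np.uint8))
        mask.voxels[5, 5, 2] = 1
        out = expand_structure(mask, 0.0)
        assert np.array_equal(out.voxels, mask.voxels)

    def test_single_voxel_anisotropic_bruteforce(self):
        # 10 mm margin on a 1 x 1 x 2 mm grid: +-10 voxels axially, +-5 slices
        grid = Grid3D(25, 25, 13, 1.0, 1.0, 2.0)
        mask = StructureMask(grid, np.zeros(grid.shape, dtype=np.uint8))
        mask.voxels[12, 12, 6] = 1
        out = expand_structure(mask, 10.0)
        ix, iy, iz = np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij")
        dist = np.sqrt(
            (1.0 * (ix - 12)) ** 2 + (1.0 * (iy - 12)) ** 2 + (2.0 * (iz - 6)) ** 2
        )
        assert np.array_equal(out.voxels.astype(bool), dist <= 10.0 + 1e-9)

    def test_monotone_in_margin(self, coarse_phantom):
        a = expand_structure(coarse_phantom.ptv, 4.0)
        b = expand_structure(coarse_phantom.ptv, 10.0)
        assert np.all(a.voxels <= b.voxels)
        assert np.all(coarse_phantom.ptv.voxels <= a.voxels)

    def test_empty_error(self):
        grid = Grid3D(4, 4, 2)
        with pytest.raises(ValueError, match="empty"):
            expand_structure(StructureMask(grid, np.zeros(grid.shape)), 5.0)


class TestFDSamples:
    def _case_and_arrays(self, seed=2):
        case = generate_phantom(seed, COARSE)
        shape = (9,) + case.grid.shape
        rng = np.random.default_rng(seed)
        fd = rng.random(shape).astype(np.float32)
        tpl = rng.random(shape).astype(np.float32)
        return case, fd, tpl

    def test_one_sample_per_roi_slice(self):
        case, fd, tpl = self._case_and_arrays()
        samples = build_fd_samples(case, fd, tpl)
        assert len(samples) == roi_slice_count(case)
        roi = case.roi().voxels
        for s in samples:
            assert roi[:, :, s.query_index].any()
            assert np.array_equal(s.roi_slice > 0, roi[:, :, s.query_index] > 0)
            assert np.all(s.target_fd >= 0)

    def test_boundary_stack_zero_padded(self):
        case, fd, tpl = self._case_and_arrays()
        samples = build_fd_samples(case, fd, tpl)
        edge = [s for s in samples if s.query_index < 3]
        assert edge, "expected an ROI slice near the inferior boundary"
        s = edge[0]
        n_missing = 3 - s.query_index
        assert np.all(s.ptv_stack[:n_missing] == 0)
        # stack ordered inferior -> superior around the query slice
        for off in range(-3, 4):
            z = s.query_index + off
            if 0 <= z < case.grid.nz:
                assert np.array_equal(s.ptv_stack[off + 3],
                                      case.ptv.voxels[:, :, z].astype(np.float32))

    def test_grid_mismatch_error(self):
        case, fd, tpl = self._case_and_arrays()
        with pytest.raises(ValueError, match="grid mismatch"):
            build_fd_samples(case, fd[:, :-1], tpl)

    def test_cohort_recount(self):
        # total sample count equals an independent recount of ROI slices
        total, recount = 0, 0
        for seed in (3, 4, 5):
            case, fd, tpl = self._case_and_arrays(seed)
            total += len(build_fd_samples(case, fd, tpl))
            roi = case.roi().voxels
            recount += int(sum(roi[:, :, z].any() for z in range(case.grid.nz)))
        assert total == recount
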