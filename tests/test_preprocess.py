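"""Calibration, masking and voxelization against exhaustive oracles."""

import numpy as np
import pytest

import finspec as fs
from finspec.envi import read_cube_dir, write_cube_dir
from finspec.preprocess import (
    CalibrationError,
    MaskingError,
    calibrate_fluorescence,
    calibrate_reflectance,
    compute_fillet_mask,
    voxel_mean_spectra,
    voxelize,
    write_pgm,
)
from finspec.synth import generate_hypercube


class TestCalibration:
    def test_flat_field_limits_and_midpoint(self):
        white = np.full((2, 2), 9.0)
        dark = np.full((2, 2), 1.0)
        assert calibrate_reflectance(dark[:, :, None], white, dark).max() == 0.0
        assert calibrate_reflectance(white[:, :, None], white, dark).min() == 1.0
        mid = calibrate_reflectance(np.full((2, 2, 1), 5.0), white, dark)
        np.testing.assert_allclose(mid, 0.5)

    def test_zero_denominator_names_location(self):
        white = np.full((2, 2), 3.0)
        dark = np.array([[3.0, 1.0], [1.0, 1.0]])
        with pytest.raises(CalibrationError, match=r"\(0, 0"):
            calibrate_reflectance(np.zeros((2, 2, 4)), white, dark)

    def test_fluorescence_scaling(self):
        dark = np.full((2, 2), 100.0)
        cube = dark[:, :, None] + 6000.0
        np.testing.assert_allclose(calibrate_fluorescence(cube, dark), 1.0)
        np.testing.assert_allclose(calibrate_fluorescence(dark[:, :, None], dark), 0.0)
        np.testing.assert_allclose(calibrate_fluorescence(cube, dark, scale=1.0), 6000.0)
        with pytest.raises(CalibrationError):
            calibrate_fluorescence(cube, dark, scale=0.0)

    def test_calibration_is_affine_order_preserving(self, rng):
        white = np.full((4, 4), 10.0)
        dark = np.zeros((4, 4))
        a = rng.uniform(0, 10, size=(4, 4, 5))
        b = a + rng.uniform(0, 1, size=a.shape)
        ca = calibrate_reflectance(a, white, dark)
        cb = calibrate_reflectance(b, white, dark)
        assert (cb >= ca).all()


class TestMask:
    def test_mask_recovers_synthetic_ellipse(self, tiny_library, fluor_mode):
        cube, refs, truth = generate_hypercube(tiny_library, "sp00", "f0", fluor_mode, seed=3)
        cal = fs.calibrate_reflectance(cube, refs["white"], refs["dark"])
        mask = compute_fillet_mask(cal)
        t = truth["fillet_mask"]
        iou = (mask & t).sum() / (mask | t).sum()
        assert iou >= 0.95

    def test_all_background_is_masking_error(self):
        with pytest.raises(MaskingError):
            compute_fillet_mask(np.zeros((20, 20, 4)))

    def test_minus_inf_threshold_masks_everything(self):
        mask = compute_fillet_mask(np.zeros((5, 5, 3)), threshold=-np.inf)
        assert mask.all()


def brute_force_voxel_oracle(cube, mask, s=10, outlier_fraction=0.10, sigma_mult=2.0,
                             min_pixels=None):
    """Independent re-derivation of the valid-voxel set, straight from the rule."""
    if min_pixels is None:
        min_pixels = (s * s) // 2
    broadband = cube.mean(axis=2)
    vals = [broadband[i, j] for i in range(cube.shape[0]) for j in range(cube.shape[1])
            if mask[i, j]]
    mu = sum(vals) / len(vals)
    sd = (sum((v - mu) ** 2 for v in vals) / len(vals)) ** 0.5
    valid = set()
    for vi in range(cube.shape[0] // s):
        for vj in range(cube.shape[1] // s):
            pix = [(i, j) for i in range(s * vi, s * vi + s) for j in range(s * vj, s * vj + s)
                   if mask[i, j]]
            if len(pix) < min_pixels:
                continue
            n_out = sum(
                1 for (i, j) in pix
                if broadband[i, j] < mu - sigma_mult * sd or broadband[i, j] > mu + sigma_mult * sd
            )
            if n_out > outlier_fraction * len(pix):
                continue
            valid.add((vi, vj))
    return valid


class TestVoxelize:
    def _boundary_cube(self, n_hot_a=10, n_hot_b=11):
        """30x30 flat cube with scripted hot pixels in two specific voxels."""
        cube = np.zeros((30, 30, 3))
        hot = 1.0
        # place exactly n_hot_a hot pixels in voxel (0,0), n_hot_b in voxel (1,1)
        coords_a = [(i, j) for i in range(10) for j in range(10)][:n_hot_a]
        coords_b = [(i, j) for i in range(10, 20) for j in range(10, 20)][:n_hot_b]
        for i, j in coords_a:
            cube[i, j] = hot
        for i, j in coords_b:
            cube[i, j] = hot
        return cube

    def test_strictly_more_than_ten_percent_excluded(self):
        cube = self._boundary_cube(10, 11)
        mask = np.ones((30, 30), dtype=bool)
        grid = voxelize(cube, mask, voxel_size=10)
        valid = {tuple(v) for v in grid.index}
        assert (0, 0) in valid  # exactly 10% outliers: retained
        assert (1, 1) not in valid  # 11%: excluded
        assert (2, 2) in valid

    def test_noiseless_uniform_fillet_keeps_all_voxels(self):
        cube = np.full((20, 20, 4), 0.6)
        grid = voxelize(cube, np.ones((20, 20), bool), voxel_size=10)
        assert grid.n_valid == 4
        np.testing.assert_allclose(grid.spectra, 0.6)

    @pytest.mark.parametrize("shape,seed", [((30, 30), 0), ((50, 50), 1), ((40, 30), 2)])
    def test_matches_exhaustive_oracle(self, shape, seed, rng):
        local = np.random.default_rng(seed)
        cube = local.uniform(0, 1, size=shape + (4,))
        # random blobby mask plus scripted extreme pixels
        mask = local.random(shape) > 0.25
        hot = local.random(shape) > 0.92
        cube[hot] = 50.0
        if not mask.any():
            mask[0, 0] = True
        grid = voxelize(cube, mask, voxel_size=10)
        got = {tuple(v) for v in grid.index}
        assert got == brute_force_voxel_oracle(cube, mask, s=10)

    def test_empty_grid_warns(self):
        cube = np.zeros((10, 10, 2))
        mask = np.zeros((10, 10), bool)
        mask[0, :3] = True  # 3 masked pixels < min_pixels
        with pytest.warns(UserWarning, match="no valid voxels"):
            grid = voxelize(cube, mask)
        assert grid.n_valid == 0


class TestVoxelMeanSpectra:
    def test_one_row_per_valid_voxel(self, fluor_mode):
        cube = np.full((20, 20, 60), 0.4)
        grid = voxelize(cube, np.ones((20, 20), bool), voxel_size=10)
        ds = voxel_mean_spectra(grid, fluor_mode, "spX", "spX_f0")
        assert ds.n_rows == grid.n_valid == 4
        assert set(ds.block("Fluor").meta["species"]) == {"spX"}

    def test_mean_of_voxel_means_equals_pixel_mean(self, fluor_mode, rng):
        cube = rng.uniform(0.2, 0.8, size=(30, 30, 60))
        mask = np.ones((30, 30), bool)
        grid = voxelize(cube, mask, voxel_size=10, outlier_fraction=1.0)
        assert grid.n_valid == 9  # all retained: equal-population voxels
        ds = voxel_mean_spectra(grid, fluor_mode, "spX", "f0")
        np.testing.assert_allclose(
            ds.block("Fluor").X.mean(axis=0), cube.reshape(-1, 60).mean(axis=0), atol=1e-9
        )


def test_envi_container_round_trip(tmp_path, tiny_library, fluor_mode):
    cube, refs, truth = generate_hypercube(tiny_library, "sp02", "sp02_f1", fluor_mode, seed=4)
    d = write_cube_dir(tmp_path / "c", cube, refs,
                       {"species": "sp02", "fillet_id": "sp02_f1", "mode": "Fluor"})
    back, brefs, meta = read_cube_dir(d)
    np.testing.assert_allclose(back, cube, atol=1e-4)  # float32 storage
    np.testing.assert_allclose(brefs["dark"], refs["dark"], atol=1e-4)
    assert meta["species"] == "sp02"


def test_preprocess_cube_round_trip(tiny_library, fluor_mode):
    """End-to-end: cube -> voxel spectra whose mean tracks the species mean."""
    cube, refs, truth = generate_hypercube(tiny_library, "sp03", "sp03_f0", fluor_mode,
                                           outlier_rate=0.02, seed=5, shape=(60, 60))
    ds = fs.preprocess_cube(cube, refs, fluor_mode, "sp03", "sp03_f0")
    assert ds.n_rows >= 4
    si = tiny_library.species.index("sp03")
    mean_spec = tiny_library.means["Fluor"][si]
    got = ds.block("Fluor").X.mean(axis=0)
    # fluorescence path: (counts - dark)/6000 with gain 4000 rescales by 2/3
    corr = np.corrcoef(got, mean_spec)[0, 1]
    assert corr > 0.99


def test_write_pgm(tmp_path):
    write_pgm(tmp_path / "m.pgm", np.array([[True, False]]))
    text = (tmp_path / "m.pgm").read_text().split()
    assert text[:4] == ["P2", "2", "1", "255"] and text[4:] == ["255", "0"]
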