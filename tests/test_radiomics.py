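"""Radiomics engine: discretization, filters, feature families, full vector."""

import numpy as np
import pytest

from fetomics.core import SummedImage, VOIMask
from fetomics.radiomics import (
    BinningSpec,
    FilterBank,
    discretize,
    extract_all,
    feature_names,
    first_order_features,
    log_filter,
    shape_features,
    texture_features,
    wavelet_decompose,
)

SPACING = (2.0, 2.0, 2.4)


class TestDiscretize:
    def test_floor_rule(self):
        vals = np.array([[[0.10, 0.16, 0.31]]])
        levels, n = discretize(vals, np.ones((1, 1, 3), bool))
        assert levels.ravel().tolist() == [1, 2, 3] and n == 3

    def test_single_bin_degenerate_but_defined(self):
        vals = np.full((3, 3, 3), 0.07)
        mask = np.ones((3, 3, 3), bool)
        levels, n = discretize(vals, mask)
        assert n == 1
        for family in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
            feats = texture_features(vals, mask, family=family)
            assert all(np.isfinite(v) for v in feats.values())

    def test_negative_values_land_in_first_bin(self):
        vals = np.array([[[-0.4, 0.02]]])
        levels, n = discretize(vals, np.ones((1, 1, 2), bool))
        assert levels.ravel().tolist() == [1, 1] and n == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_doubling_bin_width_never_increases_level_count(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((4, 4, 4)) * 3
        mask = rng.random((4, 4, 4)) < 0.8
        mask.flat[0] = True
        _, n1 = discretize(vals, mask, BinningSpec(bin_width=0.15))
        _, n2 = discretize(vals, mask, BinningSpec(bin_width=0.30))
        assert n2 <= n1


class TestFilters:
    def test_log_annihilates_constants(self):
        out = log_filter(np.full((10, 10, 8), 2.7), SPACING)
        assert np.abs(out).max() < 1e-10

    def test_log_impulse_matches_analytic_kernel(self):
        # sigma of two voxels: the sampled kernel is well resolved
        spacing = (0.25, 0.25, 0.25)
        sigma = 0.5
        vals = np.zeros((17, 17, 17))
        vals[8, 8, 8] = 1.0
        out = log_filter(vals, spacing, sigma_mm=sigma)
        xs = (np.arange(17) - 8) * spacing[0]
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        r2 = X**2 + Y**2 + Z**2
        g = np.exp(-r2 / (2 * sigma**2)) / (np.sqrt(2 * np.pi) * sigma) ** 3
        analytic = g * (r2 - 3 * sigma**2) / sigma**4
        np.testing.assert_allclose(out[4:13, 4:13, 4:13], analytic[4:13, 4:13, 4:13],
                                   atol=1e-6)

    def test_wavelet_band_count_and_grids(self):
        vals = np.random.default_rng(0).random((10, 9, 8))
        bands = wavelet_decompose(vals)
        assert len(bands) == 8
        assert all(b.shape == vals.shape for b in bands.values())

    def test_wavelet_constant_image(self):
        bands = wavelet_decompose(np.full((8, 8, 8), 3.0))
        lll = bands.pop("LLL")
        assert np.allclose(lll, lll.flat[0]) and lll.flat[0] != 0
        for name, band in bands.items():
            assert np.abs(band).max() < 1e-9, name

    def test_wavelet_step_energy_concentrates_on_edge_axis(self):
        # coif1 has vanishing moments, so a step (not a ramp) probes the
        # high-pass axis assignment
        vals = np.zeros((16, 8, 8))
        vals[8:, :, :] = 1.0
        bands = wavelet_decompose(vals)
        e = {k: float((v**2).sum()) for k, v in bands.items()}
        assert e["HLL"] > 0
        assert max(e[k] for k in e if k not in ("LLL", "HLL")) < 1e-12 * e["HLL"]


class TestFirstOrder:
    def test_hand_example(self):
        vals = np.zeros((1, 1, 3))
        vals[0, 0] = [1, 2, 3]
        f = first_order_features(vals, np.ones((1, 1, 3), bool), spacing=(1, 1, 1))
        assert f["Energy"] == 14 and f["Maximum"] == 3 and f["Mean"] == 2

    def test_constant_voi(self):
        f = first_order_features(np.full((3, 3, 3), 1.1), np.ones((3, 3, 3), bool),
                                 spacing=SPACING)
        assert f["Variance"] == pytest.approx(0.0, abs=1e-15)
        assert f["Uniformity"] == 1

    def test_invariant_to_mask_voxel_ordering(self):
        rng = np.random.default_rng(1)
        vals = rng.random((5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.5
        mask.flat[0] = True
        a = first_order_features(vals, mask, spacing=SPACING)
        b = first_order_features(vals.transpose(2, 1, 0).copy(),
                                 mask.transpose(2, 1, 0).copy(), spacing=SPACING)
        for k in a:
            if k != "TotalEnergy":  # spacing is axis-symmetric here anyway
                assert a[k] == pytest.approx(b[k], rel=1e-12), k


class TestShape:
    def test_collinear_voxels_major_axis(self):
        mask = np.zeros((5, 3, 3), bool)
        mask[1:4, 1, 1] = True
        f = shape_features(mask, (2.0, 2.0, 2.0))
        assert f["MajorAxisLength"] == pytest.approx(8.0)

    def test_cube_symmetry(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["MajorAxisLength"] == pytest.approx(f["MinorAxisLength"], abs=1e-9)
        assert f["MinorAxisLength"] == pytest.approx(f["LeastAxisLength"], abs=1e-9)

    def test_single_voxel_axis_features_zero_with_warning(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.warns(UserWarning, match="single-voxel"):
            f = shape_features(mask, SPACING)
        assert f["MajorAxisLength"] == 0.0

    def test_voxel_volume(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[:2, :2, :2] = True
        f = shape_features(mask, SPACING)
        assert f["VoxelVolume"] == pytest.approx(8 * 2.0 * 2.0 * 2.4)


class TestFullVector:
    def test_name_list_structure(self):
        names = feature_names()
        assert len(names) == 944
        assert len(set(names)) == 944
        assert sum(n.startswith("original_") for n in names) == 107
        assert sum(n.startswith("log-sigma-0.5_") for n in names) == 93
        assert sum(n.startswith("wavelet-") for n in names) == 744
        assert not any("shape" in n for n in names if not n.startswith("original"))

    def test_extraction_matches_names(self, noisefree_patient):
        fv = extract_all(noisefree_patient["summed"], noisefree_patient["tumor"])
        assert list(fv) == feature_names()
        assert all(np.isfinite(v) for v in fv.values())

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        vals = np.ones((14, 14, 12))
        vals[3:8, 3:8, 3:7] += rng.random((5, 5, 4))
        mask = np.zeros((14, 14, 12), bool)
        mask[3:8, 3:8, 3:7] = True
        shifted_vals = np.roll(vals, (2, 1, 2), axis=(0, 1, 2))
        shifted_mask = np.roll(mask, (2, 1, 2), axis=(0, 1, 2))
        a = extract_all(SummedImage(vals, SPACING), VOIMask(mask, SPACING, "tumor@1.6", 1.6))
        b = extract_all(SummedImage(shifted_vals, SPACING),
                        VOIMask(shifted_mask, SPACING, "tumor@1.6", 1.6))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-7, abs=1e-9), k
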