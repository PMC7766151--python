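"""Summed images, background sphere, TBR auto-contour and the peak sphere."""

import numpy as np
import pytest

from fetomics.core import SummedImage, VOIMask, make_frame_schedule, DynamicPETSeries
from fetomics.phantom import PhantomSpec, default_kinetics, simulate_patient
from fetomics.segmentation import (
    AUGMENTATION_THRESHOLDS,
    augment_segmentations,
    autocontour,
    background_voi,
    peak_sphere,
    sum_window,
)

SPACING = (2.0, 2.0, 2.4)


def _series_from_frames(frame_values):
    """Constant-per-frame series on a small grid."""
    vals = np.ones((4, 4, 4, 14)) * np.asarray(frame_values)[None, None, None, :]
    return DynamicPETSeries(vals, SPACING, make_frame_schedule())


class TestSumWindow:
    def test_constant_series_preserved(self):
        series = _series_from_frames([3.0] * 14)
        assert sum_window(series).values == pytest.approx(3.0)

    def test_weighted_mean_of_window_frames(self):
        frames = [0.0] * 10 + [1.0, 2.0, 3.0, 4.0]
        assert sum_window(series := _series_from_frames(frames)).values == pytest.approx(2.5)
        # default window uses exactly the four 5-minute frames
        sched = series.schedule
        inside = (sched.starts >= 20) & (sched.ends <= 40)
        assert inside.sum() == 4

    def test_non_aligned_window_rejected(self):
        series = _series_from_frames([1.0] * 14)
        with pytest.raises(ValueError, match="align"):
            sum_window(series, start=21.0, end=40.0)


class TestBackgroundVOI:
    def test_volume_near_14_ml(self):
        image = SummedImage(np.ones((40, 40, 30)), SPACING)
        voi = background_voi(image, center_mm=(40.0, 40.0, 33.6))
        assert 13.2 <= voi.volume_ml <= 15.1

    def test_uniform_image_mean(self):
        image = SummedImage(np.full((40, 40, 30), 1.7), SPACING)
        voi = background_voi(image, center_mm=(40.0, 40.0, 33.6))
        assert image.values[voi.mask].mean() == pytest.approx(1.7)

    def test_clipped_sphere_rejected(self):
        image = SummedImage(np.ones((40, 40, 30)), SPACING)
        with pytest.raises(ValueError, match="clipped"):
            background_voi(image, center_mm=(5.0, 40.0, 33.6))


class TestAutocontour:
    def test_subthreshold_image_gives_empty_mask(self):
        image = SummedImage(np.ones((8, 8, 8)), SPACING)
        voi = autocontour(image, bg_mean=1.0, threshold=1.6)
        assert voi.n_voxels == 0

    def test_threshold_is_inclusive(self):
        vals = np.ones((8, 8, 8))
        vals[2:5, 2:5, 2:5] = 1.6  # exactly 1.6 x background
        voi = autocontour(SummedImage(vals, SPACING), bg_mean=1.0)
        assert voi.n_voxels == 27

    def test_largest_component_kept(self):
        vals = np.ones((12, 8, 8))
        vals[0:2, 0:5, 0:1] = 2.0  # 10-voxel blob
        vals[8:10, 0:2, 0:1] = 2.0  # 4-voxel blob
        voi = autocontour(SummedImage(vals, SPACING), bg_mean=1.0)
        assert voi.n_voxels == 10
        assert voi.mask[0, 0, 0] and not voi.mask[8, 0, 0]

    def test_augmentation_nested_and_counted(self, noisefree_patient):
        masks = augment_segmentations(
            noisefree_patient["summed"], noisefree_patient["bg_mean"]
        )
        assert [m.threshold for m in masks] == list(AUGMENTATION_THRESHOLDS)
        m14, m16, m18 = (m.mask for m in masks)
        assert (m18 <= m16).all() and (m16 <= m14).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_threshold_monotonicity_on_random_phantoms(self, seed):
        spec = PhantomSpec(seed=seed)
        series, gt = simulate_patient(spec, default_kinetics("EP"), 5000 + seed)
        summed = sum_window(series)
        bg = background_voi(summed, gt.bg_center_mm)
        bg_mean = float(summed.values[bg.mask].mean())
        masks = augment_segmentations(summed, bg_mean)
        assert (masks[2].mask <= masks[1].mask).all()
        assert (masks[1].mask <= masks[0].mask).all()
        # every tumour voxel reaches its threshold, hence TBRmean >= threshold
        for m in masks:
            if m.n_voxels:
                assert summed.values[m.mask].min() / bg_mean >= m.threshold - 1e-9
        # background and tumour VOIs are disjoint by construction
        assert not (masks[0].mask & bg.mask).any()


class TestPeakSphere:
    def test_sphere_centered_on_hot_voxel(self):
        vals = np.ones((20, 20, 16))
        vals[10, 10, 8] = 5.0
        image = SummedImage(vals, SPACING)
        within = VOIMask(vals > 1.0, SPACING, "tumor@1.6", 1.6)
        sphere = peak_sphere(image, within)
        assert sphere.mask[10, 10, 8]
        assert 1.9 <= sphere.volume_ml <= 2.4  # 16 mm sphere ~ 2.14 mL

    def test_tie_broken_by_lowest_linear_index(self):
        vals = np.ones((20, 20, 16)) * 2.0
        image = SummedImage(vals, SPACING)
        within = np.zeros((20, 20, 16), bool)
        within[5, 5, 5] = within[10, 10, 10] = True
        sphere = peak_sphere(image, VOIMask(within, SPACING, "tumor@1.6", 1.6))
        assert sphere.mask[5, 5, 5] and not sphere.mask[10, 10, 10]

    def test_empty_tumor_rejected(self):
        image = SummedImage(np.ones((8, 8, 8)), SPACING)
        empty = VOIMask(np.zeros((8, 8, 8), bool), SPACING, "tumor@1.6", 1.6)
        with pytest.raises(ValueError, match="no tumor voxels"):
            peak_sphere(image, empty)
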