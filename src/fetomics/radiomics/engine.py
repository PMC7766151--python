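"""Assembly of the full 944-feature vector per VOI.

107 features on the original (summed 20-40 min) image and 93 on each of the
9 filtered images (shape features are computed once, from the unfiltered
mask).  Feature names follow the ``<image>_<family>_<Feature>`` scheme,
e.g. ``original_shape_MajorAxisLength`` or ``wavelet-HLL_glcm_Contrast``;
the name list is stable and ordered.
"""

from __future__ import annotations

from collections import OrderedDict
from collections.abc import Iterable

import numpy as np
import pandas as pd

from ..core import SummedImage, VOIMask
from .binning import BinningSpec
from .filters import FilterBank, WAVELET_BANDS
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import FAMILY_NAMES, TEXTURE_FAMILIES, texture_features

__all__ = ["extract_all", "extract_cohort", "feature_names", "N_FEATURES"]

N_FEATURES = 944


def _image_keys(filters: FilterBank) -> list[str]:
    return (
        ["original", f"log-sigma-{filters.log_sigma:g}"]
        + [f"wavelet-{b}" for b in WAVELET_BANDS]
    )


def feature_names(filters: FilterBank | None = None) -> list[str]:
    """The canonical, ordered list of the 944 feature names."""
    filters = filters or FilterBank()
    names: list[str] = []
    for img in _image_keys(filters):
        names += [f"{img}_firstorder_{n}" for n in FIRST_ORDER_NAMES]
        if img == "original":
            names += [f"original_shape_{n}" for n in SHAPE_NAMES]
        for fam in TEXTURE_FAMILIES:
            names += [f"{img}_{fam}_{n}" for n in FAMILY_NAMES[fam]]
    assert len(names) == N_FEATURES
    return names


def extract_all(
    summed: SummedImage,
    mask: VOIMask,
    binning: BinningSpec | None = None,
    filters: FilterBank | None = None,
    _filtered: dict[str, np.ndarray] | None = None,
) -> "OrderedDict[str, float]":
    """All 944 features of one VOI.

    ``_filtered`` lets a caller reuse precomputed filtered images when
    extracting several VOIs of the same patient (the filters depend only on
    the image, not on the mask).
    """
    if not mask.mask.any():
        raise ValueError("mask is empty")
    binning = binning or BinningSpec()
    filters = filters or FilterBank()
    if _filtered is None:
        _filtered = filters.apply(summed.values, summed.voxel_size)
    images = {"original": summed.values, **_filtered}

    out: "OrderedDict[str, float]" = OrderedDict()
    for img in _image_keys(filters):
        values = images[img]
        fo = first_order_features(values, mask.mask, binning, summed.voxel_size)
        for n in FIRST_ORDER_NAMES:
            out[f"{img}_firstorder_{n}"] = fo[n]
        if img == "original":
            sh = shape_features(mask.mask, summed.voxel_size)
            for n in SHAPE_NAMES:
                out[f"original_shape_{n}"] = sh[n]
        for fam in TEXTURE_FAMILIES:
            tf = texture_features(values, mask.mask, binning, family=fam)
            for n in FAMILY_NAMES[fam]:
                out[f"{img}_{fam}_{n}"] = tf[n]
    assert len(out) == N_FEATURES
    return out


def extract_cohort(
    patients: Iterable[tuple],
    thresholds: tuple[float, ...] = (1.4, 1.6, 1.8),
    binning: BinningSpec | None = None,
    filters: FilterBank | None = None,
) -> pd.DataFrame:
    """Feature table for a simulated cohort: one row per (patient, threshold).

    ``patients`` is an iterable of ``(DynamicPETSeries, GroundTruth)`` pairs
    as produced by :func:`fetomics.phantom.simulate_cohort`.  Filtered images
    are computed once per patient and shared across the three augmented
    segmentations.
    """
    from ..segmentation import autocontour, background_voi, sum_window

    filters = filters or FilterBank()
    rows = []
    for series, gt in patients:
        summed = sum_window(series)
        bg = background_voi(summed, gt.bg_center_mm)
        bg_mean = float(summed.values[bg.mask].mean())
        filtered = filters.apply(summed.values, summed.voxel_size)
        for thr in thresholds:
            voi = autocontour(summed, bg_mean, threshold=thr)
            if not voi.mask.any():
                raise ValueError(
                    f"empty tumor VOI for {gt.patient_id} at threshold {thr}"
                )
            feats = extract_all(summed, voi, binning, filters, _filtered=filtered)
            row = {
                "patient_id": gt.patient_id,
                "segmentation_threshold": thr,
                "label": gt.label,
            }
            row.update(feats)
            rows.append(row)
    return pd.DataFrame.from_records(rows)
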