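"""Background VOI, TBR iso-contour tumour segmentation, and the 16 mm peak sphere.

The tumour auto-contour keeps every voxel whose summed-image value divided by
the background mean reaches the TBR threshold (inclusive), restricted to the
largest 26-connected component.  Augmentation produces the three nested
segmentations at TBR 1.4 / 1.6 / 1.8 used to triple the dataset.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import DynamicPETSeries, SummedImage, VOIMask

__all__ = [
    "sum_window",
    "background_voi",
    "autocontour",
    "augment_segmentations",
    "peak_sphere",
    "AUGMENTATION_THRESHOLDS",
    "DEFAULT_TBR_THRESHOLD",
]

DEFAULT_TBR_THRESHOLD = 1.6
#: the 10% lower / nominal / 10% higher iso-contour thresholds
AUGMENTATION_THRESHOLDS = (1.4, 1.6, 1.8)

_CONN26 = np.ones((3, 3, 3), dtype=bool)
# tolerance for "or more" threshold comparisons under floating point
_EPS = 1e-9


def sum_window(
    series: DynamicPETSeries, start: float = 20.0, end: float = 40.0
) -> SummedImage:
    """Duration-weighted mean of the frames whose intervals tile [start, end].

    The window boundaries must coincide with frame boundaries.
    """
    sched = series.schedule
    inside = (sched.starts >= start - _EPS) & (sched.ends <= end + _EPS)
    if not inside.any():
        raise ValueError(f"no frames inside window [{start}, {end}] min")
    starts = sched.starts[inside]
    ends = sched.ends[inside]
    if abs(starts.min() - start) > _EPS or abs(ends.max() - end) > _EPS:
        raise ValueError(
            f"window [{start}, {end}] min does not align with frame boundaries"
        )
    dur = sched.durations[inside]
    frames = series.values[..., inside]
    values = np.tensordot(frames, dur, axes=([3], [0])) / dur.sum()
    return SummedImage(values=values, voxel_size=series.voxel_size, window=(start, end))


def _voxel_center_sphere(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    radius_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within radius of center_mm."""
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    dx2 = (coords[0] - center_mm[0]) ** 2
    dy2 = (coords[1] - center_mm[1]) ** 2
    dz2 = (coords[2] - center_mm[2]) ** 2
    d2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
    return d2 <= radius_mm**2 + _EPS


def background_voi(
    image: SummedImage, center_mm, diameter_mm: float = 30.0
) -> VOIMask:
    """Spherical background VOI (default diameter 30 mm / ~14 mL) in healthy brain.

    ``center_mm`` is the sphere center in world coordinates.  Raises if the
    sphere would be clipped by the grid.
    """
    center = np.asarray(center_mm, dtype=float)
    radius = diameter_mm / 2.0
    shape = image.values.shape
    extent = [(n - 1) * s for n, s in zip(shape, image.voxel_size)]
    for ax in range(3):
        if center[ax] - radius < -_EPS or center[ax] + radius > extent[ax] + _EPS:
            raise ValueError("background sphere clipped by image grid")
    mask = _voxel_center_sphere(shape, image.voxel_size, center, radius)
    return VOIMask(mask=mask, voxel_size=image.voxel_size, provenance="background")


def autocontour(
    image: SummedImage,
    bg_mean: float,
    threshold: float = DEFAULT_TBR_THRESHOLD,
    search_region: VOIMask | None = None,
) -> VOIMask:
    """TBR iso-contour tumour VOI: value / bg_mean >= threshold, largest component.

    Voxels at exactly the threshold are included ("1.6 or more").  The result
    is restricted to the largest 26-connected component (ties broken by the
    lowest component label, i.e. the component encountered first in scan
    order).  An empty mask is allowed and returned as such.
    """
    if bg_mean <= 0:
        raise ValueError("background mean must be positive")
    above = image.values >= threshold * bg_mean - _EPS
    if search_region is not None:
        above &= search_region.mask
    if above.any():
        labels, n = ndimage.label(above, structure=_CONN26)
        if n > 1:
            sizes = np.bincount(labels.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1  # argmax -> lowest label on ties
            above = labels == keep
    return VOIMask(
        mask=above,
        voxel_size=image.voxel_size,
        provenance=f"tumor@{threshold:g}",
        threshold=float(threshold),
    )


def augment_segmentations(
    image: SummedImage,
    bg_mean: float,
    search_region: VOIMask | None = None,
    thresholds: tuple[float, ...] = AUGMENTATION_THRESHOLDS,
) -> list[VOIMask]:
    """The three tumour segmentations at TBR 1.4 / 1.6 / 1.8 (nested)."""
    return [
        autocontour(image, bg_mean, threshold=t, search_region=search_region)
        for t in thresholds
    ]


def peak_sphere(
    image: SummedImage, within: VOIMask, diameter_mm: float = 16.0
) -> VOIMask:
    """16 mm-diameter sphere centered on the hottest voxel inside ``within``.

    The sphere may extend outside ``within`` (it is not clipped to the tumour
    VOI) but is intersected with the image grid.  Argmax ties are broken by
    the lowest linear (C-order) index.
    """
    if not within.mask.any():
        raise ValueError("no tumor voxels")
    masked = np.where(within.mask, image.values, -np.inf)
    flat_idx = int(np.argmax(masked))  # first max in C order
    center_idx = np.unravel_index(flat_idx, image.values.shape)
    center_mm = np.array(center_idx, dtype=float) * np.array(image.voxel_size)
    mask = _voxel_center_sphere(
        image.values.shape, image.voxel_size, center_mm, diameter_mm / 2.0
    )
    return VOIMask(mask=mask, voxel_size=image.voxel_size, provenance="peak_sphere")
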