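"""Conventional static and dynamic FET PET parameters.

TBRmean is the tumour-VOI mean SUV over the background-VOI mean SUV on the
20-40 min summed image.  TBRmax divides the mean of a 16 mm sphere centered
on the hottest tumour voxel (not the single max voxel) by the background
mean.  TTP and slope are read from the time-activity curve of that sphere:
TTP is the mid-time of the hottest frame (steadily increasing curves peak at
the end of the acquisition, 37.5 min) and slope is the OLS regression of the
20-40 min curve in SUV per hour.
"""

from __future__ import annotations

import numpy as np

from .core import ConventionalParams, DynamicPETSeries, SummedImage, TACurve, VOIMask
from .segmentation import peak_sphere, sum_window

__all__ = [
    "tbr_mean",
    "tbr_max",
    "extract_tac",
    "ttp",
    "slope",
    "conventional_params",
]

_EPS = 1e-9


def _voi_mean(image: SummedImage, voi: VOIMask, name: str) -> float:
    if not voi.mask.any():
        raise ValueError(f"empty {name} VOI")
    return float(image.values[voi.mask].mean())


def tbr_mean(summed: SummedImage, tumor_voi: VOIMask, bg_voi: VOIMask) -> float:
    """Mean SUV of the tumour VOI divided by the background mean SUV."""
    return _voi_mean(summed, tumor_voi, "tumor") / _voi_mean(summed, bg_voi, "background")


def tbr_max(summed: SummedImage, peak_voi: VOIMask, bg_voi: VOIMask) -> float:
    """Mean SUV of the 16 mm peak sphere divided by the background mean SUV."""
    return _voi_mean(summed, peak_voi, "peak") / _voi_mean(summed, bg_voi, "background")


def extract_tac(series: DynamicPETSeries, voi: VOIMask) -> TACurve:
    """Per-frame mean SUV within the VOI."""
    if not voi.mask.any():
        raise ValueError("empty VOI")
    means = series.values[voi.mask, :].mean(axis=0)
    return TACurve(
        mid_times=series.schedule.mid_times,
        mean_suv=means,
        voi_provenance=voi.provenance,
    )


def ttp(tac: TACurve) -> float:
    """Time-to-peak: mid-time of the frame with maximal mean SUV.

    Ties are broken toward the earlier frame.  If the curve is non-decreasing
    over the last three frames and the global maximum is attained in the final
    frame (steadily increasing uptake), the end of the acquisition is
    returned.
    """
    v = tac.mean_suv
    vmax = v.max()
    tail = v[-3:]
    if np.all(np.diff(tail) >= -_EPS) and v[-1] >= vmax - _EPS:
        return float(tac.mid_times[-1])
    return float(tac.mid_times[int(np.argmax(v))])


def slope(tac: TACurve, window: tuple[float, float] = (20.0, 40.0)) -> float:
    """OLS slope of the TAC over frame mid-times inside the window, in SUV/h."""
    sel = (tac.mid_times >= window[0]) & (tac.mid_times <= window[1])
    if sel.sum() < 2:
        raise ValueError("need at least 2 frames inside the regression window")
    t = tac.mid_times[sel]
    y = tac.mean_suv[sel]
    slope_per_min = np.polyfit(t, y, 1)[0]
    return float(slope_per_min * 60.0)


def conventional_params(
    series: DynamicPETSeries,
    tumor_voi: VOIMask,
    bg_voi: VOIMask,
    summed: SummedImage | None = None,
) -> ConventionalParams:
    """Compute all four conventional parameters for one patient."""
    if summed is None:
        summed = sum_window(series)
    peak = peak_sphere(summed, within=tumor_voi)
    tac = extract_tac(series, peak)
    return ConventionalParams(
        tbr_mean=tbr_mean(summed, tumor_voi, bg_voi),
        tbr_max=tbr_max(summed, peak, bg_voi),
        ttp=ttp(tac),
        slope=slope(tac),
    )
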