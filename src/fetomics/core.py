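"""Shared containers for dynamic FET PET volumes, VOI masks, and acquisition timing.

All grids are voxel-index based (0-based); world coordinates of voxel ``i``
are ``i * spacing`` in millimetres.  Masks and images always share the grid
of the series they were derived from -- there is no resampling anywhere in
this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSchedule",
    "make_frame_schedule",
    "DynamicPETSeries",
    "SummedImage",
    "VOIMask",
    "TACurve",
    "ConventionalParams",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition timeline of a dynamic PET scan.

    Times are minutes post-injection.  Frames must be contiguous,
    non-overlapping, and start at 0.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.shape != durations.shape or starts.ndim != 1:
            raise ValueError("starts and durations must be 1-D arrays of equal length")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be positive")
        if starts[0] != 0.0:
            raise ValueError("first frame must start at 0 min")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-points in minutes."""
        return self.starts + self.durations / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    def __len__(self) -> int:
        return self.starts.size


def make_frame_schedule() -> FrameSchedule:
    """The 14-frame 0-40 min schedule: 5 x 1 min, 5 x 3 min, 4 x 5 min."""
    durations = np.array([1.0] * 5 + [3.0] * 5 + [5.0] * 4)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts=starts, durations=durations)


@dataclass
class DynamicPETSeries:
    """4-D SUV volume (x, y, z, frame) with voxel spacing in mm."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError(f"expected 4D array, got {self.values.ndim}D")
        if self.values.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame count {self.values.shape[3]} does not match schedule "
                f"length {len(self.schedule)}"
            )
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]


@dataclass
class SummedImage:
    """3-D SUV image: duration-weighted mean of frames inside a time window."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    window: tuple[float, float] = (20.0, 40.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D array, got {self.values.ndim}D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)


@dataclass
class VOIMask:
    """Boolean 3-D volume of interest on the grid of its source image.

    ``provenance`` records how the mask was made: ``"background"``,
    ``"tumor@<threshold>"``, or ``"peak_sphere"``.  ``threshold`` carries the
    TBR iso-contour value for tumour masks.
    """

    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.mask.ndim}D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if not self.provenance.startswith("tumor") and not self.mask.any():
            raise ValueError(f"{self.provenance} VOI must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        """Physical volume in millilitres."""
        vv = float(np.prod(self.voxel_size))  # mm^3
        return self.n_voxels * vv / 1000.0


@dataclass
class TACurve:
    """Mean-SUV time-activity curve of a VOI."""

    mid_times: np.ndarray
    mean_suv: np.ndarray
    voi_provenance: str = ""

    def __post_init__(self) -> None:
        self.mid_times = np.asarray(self.mid_times, dtype=float)
        self.mean_suv = np.asarray(self.mean_suv, dtype=float)
        if self.mid_times.shape != self.mean_suv.shape:
            raise ValueError("mid_times and mean_suv must have equal length")
        if not np.all(np.isfinite(self.mean_suv)):
            raise ValueError("mean_suv must be finite")


@dataclass(frozen=True)
class ConventionalParams:
    """The four conventional FET PET parameters of one patient."""

    tbr_mean: float
    tbr_max: float
    ttp: float  # minutes, on the frame mid-time grid
    slope: float  # SUV/h over the 20-40 min window

    def as_dict(self) -> dict[str, float]:
        return {
            "tbr_mean": self.tbr_mean,
            "tbr_max": self.tbr_max,
            "ttp": self.ttp,
            "slope": self.slope,
        }
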