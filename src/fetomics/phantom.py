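"""Synthetic dynamic FET PET cohort generator with known kinetic ground truth.

The phantom emulates the study conditions this package analyses: a 0-40 min
dynamic acquisition (14 frames: 5 x 1, 5 x 3, 4 x 5 min) on a
2.0 x 2.0 x 2.4 mm grid, with one amino-acid-avid lesion per patient and a
homogeneous background at SUV 1.  Two kinetic classes are generated:

* early tumour progression (EP): hotter lesions (peak TBR ~ 2.6 +/- 0.6),
  strong intralesional heterogeneity, time-activity curves peaking early
  (8th-10th frame) and then declining;
* pseudoprogression (PSP): cooler (peak TBR ~ 2.0 +/- 0.3), nearly
  homogeneous lesions whose uptake keeps increasing to the end of the
  acquisition.

The lesion is an ellipsoid with a flat plateau (75% of each semi-axis) and a
cosine taper to the background, modulated by a smooth multiplicative random
field (the heterogeneity).  The field is normalised so the hottest voxel of
the noise-free 20-40 min summed image equals the drawn peak TBR exactly.
Per-frame Gaussian noise has standard deviation
``noise_sd_per_minute / sqrt(frame duration)``, mimicking count statistics.

Peak-TBR draws come from a normal truncated below at TBR 1.85 (lesions below
that would produce an empty VOI at the highest augmentation iso-contour,
TBR 1.8) whose location is solved so the class mean equals ``peak_tbr_mean``
despite the truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .core import DynamicPETSeries, FrameSchedule, make_frame_schedule

__all__ = [
    "KineticClassParams",
    "PhantomSpec",
    "GroundTruth",
    "default_kinetics",
    "make_frame_schedule",
    "simulate_patient",
    "simulate_cohort",
    "patient_seed_for",
]

#: lesions below this peak TBR would yield an empty VOI at the highest
#: augmentation iso-contour (TBR 1.8)
MIN_PEAK_TBR = 1.85
#: fraction of each semi-axis occupied by the flat plateau
_PLATEAU_FRACTION = 0.75
#: minimum effective 20-40 min slope (SUV/h) for the "late" TAC mode, so the
#: curve genuinely increases through the last frame
_MIN_LATE_SLOPE = 0.05


@dataclass(frozen=True)
class KineticClassParams:
    """Class-conditional generative parameters for one diagnosis."""

    label: str  # "EP" or "PSP"
    peak_tbr_mean: float
    peak_tbr_sd: float
    ttp_mode: str  # "early" or "late"
    slope_mean: float  # SUV/h over 20-40 min
    slope_sd: float
    heterogeneity_amplitude: float  # fraction of lesion SUV
    heterogeneity_length: float  # mm

    def __post_init__(self) -> None:
        if self.label not in ("EP", "PSP"):
            raise ValueError("label must be 'EP' or 'PSP'")
        if self.ttp_mode not in ("early", "late"):
            raise ValueError("ttp_mode must be 'early' or 'late'")
        if self.peak_tbr_mean <= 1.6:
            raise ValueError("peak_tbr_mean must exceed 1.6 (lesion must segment)")
        if not 0.0 <= self.heterogeneity_amplitude <= 0.5:
            raise ValueError("heterogeneity_amplitude must be in [0, 0.5]")


def default_kinetics(label: str) -> KineticClassParams:
    """Default kinetic parameters matching the two study groups."""
    if label == "EP":
        return KineticClassParams(
            label="EP",
            peak_tbr_mean=2.6,
            peak_tbr_sd=0.6,
            ttp_mode="early",
            slope_mean=-0.2,
            slope_sd=0.8,
            heterogeneity_amplitude=0.25,
            heterogeneity_length=6.0,
        )
    if label == "PSP":
        return KineticClassParams(
            label="PSP",
            peak_tbr_mean=2.0,
            peak_tbr_sd=0.3,
            ttp_mode="late",
            slope_mean=0.4,
            slope_sd=0.5,
            heterogeneity_amplitude=0.08,
            heterogeneity_length=12.0,
        )
    raise ValueError("label must be 'EP' or 'PSP'")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, cohort composition and noise level of a simulated cohort."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.4)
    n_ep: int = 18
    n_psp: int = 16
    background_suv: float = 1.0
    lesion_radius_range: tuple[float, float] = (12.5, 15.0)
    noise_sd_per_minute: float = 0.15  # SUV * sqrt(min)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ep + self.n_psp < 2:
            raise ValueError("need at least 2 patients")
        extent = [(n - 1) * s for n, s in zip(self.grid_shape, self.voxel_size)]
        if min(extent) < 60.0:
            raise ValueError(
                "grid too small: must hold a 30 mm background sphere and the lesion"
            )


@dataclass
class GroundTruth:
    """Per-patient generative ground truth."""

    patient_id: str
    label: str
    true_peak_tbr: float
    ttp_target: float  # minutes (frame mid-time)
    slope_target: float  # effective SUV/h over 20-40 min
    seed: int
    lesion_mask: np.ndarray = field(repr=False)
    lesion_center_mm: np.ndarray = field(repr=False)
    bg_center_mm: np.ndarray = field(repr=False)


def patient_seed_for(cohort_seed: int, index: int) -> int:
    """Deterministic per-patient seed derived from (cohort seed, patient index)."""
    ss = np.random.SeedSequence([int(cohort_seed), int(index)])
    return int(ss.generate_state(1)[0] % np.uint32(2**31))


@lru_cache(maxsize=None)
def _truncated_normal_location(mean: float, sd: float, lower: float) -> float:
    """Location of a normal truncated below at ``lower`` with the given mean."""

    def trunc_mean(loc: float) -> float:
        a = (lower - loc) / sd
        # E[X | X > lower] = loc + sd * phi(a) / (1 - Phi(a))
        return loc + sd * stats.norm.pdf(a) / stats.norm.sf(a)

    return float(
        optimize.brentq(lambda m: trunc_mean(m) - mean, mean - 4 * sd, mean + sd)
    )


def _draw_peak_tbr(rng: np.random.Generator, kin: KineticClassParams) -> float:
    loc = _truncated_normal_location(kin.peak_tbr_mean, kin.peak_tbr_sd, MIN_PEAK_TBR)
    a = (MIN_PEAK_TBR - loc) / kin.peak_tbr_sd
    return float(
        stats.truncnorm.rvs(a, np.inf, loc=loc, scale=kin.peak_tbr_sd, random_state=rng)
    )


def _lesion_envelope(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    semi_axes_mm: np.ndarray,
    origin_idx: tuple[int, int, int] = (0, 0, 0),
) -> tuple[np.ndarray, np.ndarray]:
    """Plateau + cosine-taper ellipsoid profile; returns (envelope, rho).

    ``origin_idx`` offsets the voxel grid, so the profile can be evaluated on
    a sub-box of the full volume.
    """
    coords = [(np.arange(n) + o) * s for n, s, o in zip(shape, spacing, origin_idx)]
    nx = (coords[0] - center_mm[0]) / semi_axes_mm[0]
    ny = (coords[1] - center_mm[1]) / semi_axes_mm[1]
    nz = (coords[2] - center_mm[2]) / semi_axes_mm[2]
    rho = np.sqrt(
        nx[:, None, None] ** 2 + ny[None, :, None] ** 2 + nz[None, None, :] ** 2
    )
    env = np.zeros(shape)
    plateau = rho <= _PLATEAU_FRACTION
    taper = (rho > _PLATEAU_FRACTION) & (rho <= 1.0)
    env[plateau] = 1.0
    env[taper] = 0.5 * (
        1.0 + np.cos(np.pi * (rho[taper] - _PLATEAU_FRACTION) / (1.0 - _PLATEAU_FRACTION))
    )
    return env, rho


def _heterogeneity_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    length_mm: float,
    lesion: np.ndarray,
) -> np.ndarray:
    """Smooth zero-mean field, normalised to maximum 1 over the lesion."""
    white = rng.standard_normal(shape)
    sigma_vox = [length_mm / s for s in spacing]
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    f = f - f[lesion].mean()
    fmax = f[lesion].max()
    if fmax <= 1e-9:  # pathological draw; fall back to a flat lesion
        return np.zeros(shape)
    return f / fmax


def _tac_profile(
    schedule: FrameSchedule,
    mode: str,
    slope_suv_h: float,
    excess_suv: float,
    ttp_target: float,
) -> np.ndarray:
    """Multiplicative time profile g at frame mid-times.

    Normalised so the duration-weighted mean over the 20-40 min frames is 1,
    hence the summed image equals the noise-free spatial profile exactly.
    ``excess_suv`` is the lesion SUV above background at the hottest voxel:
    only the excess is modulated in time, so the target 20-40 min slope of
    the peak-sphere TAC fixes the relative slope as slope / (60 * excess).
    """
    mids = schedule.mid_times
    m = slope_suv_h / 60.0 / excess_suv  # relative slope per minute
    g = np.empty_like(mids)
    window = mids >= 22.5 - 1e-9
    g[window] = 1.0 + m * (mids[window] - 30.0)
    g11 = 1.0 + m * (22.5 - 30.0)
    if mode == "late":
        nodes_t = np.array([mids[0], 22.5])
        nodes_g = np.array([0.3, g11])
    else:
        g_peak = 1.15 * max(float(g[window].max()), 1.0)
        nodes_t = np.array([mids[0], ttp_target, 22.5])
        nodes_g = np.array([0.3, g_peak, g11])
    g[~window] = np.interp(mids[~window], nodes_t, nodes_g)
    return g


def simulate_patient(
    spec: PhantomSpec,
    kinetics: KineticClassParams,
    patient_seed: int,
    patient_id: str = "P00",
) -> tuple[DynamicPETSeries, GroundTruth]:
    """Simulate one patient's dynamic series and its ground truth."""
    rng = np.random.default_rng(patient_seed)
    schedule = make_frame_schedule()
    shape = spec.grid_shape
    spacing = spec.voxel_size
    extent = np.array([(n - 1) * s for n, s in zip(shape, spacing)])

    # geometry: lesion in one hemisphere, background sphere mirrored across
    # the x midplane
    jitter = rng.uniform(-4.0, 4.0, size=3)
    lesion_center = np.array(
        [0.75 * extent[0], 0.5 * extent[1], 0.5 * extent[2]]
    ) + jitter
    bg_center = lesion_center.copy()
    bg_center[0] = extent[0] - lesion_center[0]

    radius = rng.uniform(*spec.lesion_radius_range)
    semi_axes = radius * np.array([1.0, rng.uniform(0.9, 1.0), rng.uniform(0.9, 1.0)])

    if np.linalg.norm(lesion_center - bg_center) < semi_axes.max() + 15.0 + 2.0:
        raise ValueError("geometry conflict: lesion overlaps background-sphere region")
    for ax in range(3):
        if (
            lesion_center[ax] - semi_axes.max() < 0
            or lesion_center[ax] + semi_axes.max() > extent[ax]
        ):
            raise ValueError("geometry conflict: lesion clipped by grid")

    # lesion quantities live on a padded bounding box (the padding gives the
    # heterogeneity filter room; outside the box the volume is pure background)
    pad_mm = 2.0 * kinetics.heterogeneity_length + 2.0 * max(spacing)
    lo = [
        max(0, int(np.floor((c - semi_axes.max() - pad_mm) / s)))
        for c, s in zip(lesion_center, spacing)
    ]
    hi = [
        min(n, int(np.ceil((c + semi_axes.max() + pad_mm) / s)) + 1)
        for c, s, n in zip(lesion_center, spacing, shape)
    ]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    box_shape = tuple(b - a for a, b in zip(lo, hi))

    env, rho = _lesion_envelope(
        box_shape, spacing, lesion_center, semi_axes, origin_idx=tuple(lo)
    )
    lesion_box = rho <= 1.0
    f = _heterogeneity_field(
        rng, box_shape, spacing, kinetics.heterogeneity_length, lesion_box
    )
    amp = kinetics.heterogeneity_amplitude
    modulation = np.clip((1.0 + amp * f) / (1.0 + amp), 0.1, None)
    # flat hot core (rho <= 0.6, blended out by 0.75) so the hottest voxel and
    # the 16 mm peak sphere sit at the lesion center, not at a random field max
    core_w = np.clip((_PLATEAU_FRACTION - rho) / 0.15, 0.0, 1.0)
    modulation = core_w + (1.0 - core_w) * modulation
    excess = env * modulation  # max is exactly 1 on the core
    center_idx = tuple(
        int(np.clip(round(c / s), 0, n - 1)) - o
        for c, s, n, o in zip(lesion_center, spacing, shape, lo)
    )
    excess[center_idx] *= 1.0001  # pin the argmax deterministically
    excess /= excess.max()  # hottest voxel carries exactly the drawn peak TBR

    peak_tbr = _draw_peak_tbr(rng, kinetics)
    bg = spec.background_suv

    slope_drawn = rng.normal(kinetics.slope_mean, kinetics.slope_sd)
    if kinetics.ttp_mode == "late":
        slope_eff = max(slope_drawn, _MIN_LATE_SLOPE)
        ttp_target = float(schedule.mid_times[-1])
    else:
        slope_eff = slope_drawn
        ttp_target = float(schedule.mid_times[rng.integers(7, 10)])  # frames 8-10

    g = _tac_profile(
        schedule, kinetics.ttp_mode, slope_eff, (peak_tbr - 1.0) * bg, ttp_target
    )

    n_frames = len(schedule)
    if spec.noise_sd_per_minute > 0:
        frame_sd = (spec.noise_sd_per_minute / np.sqrt(schedule.durations)).astype(
            np.float32
        )
        values = rng.standard_normal((*shape, n_frames), dtype=np.float32)
        values *= frame_sd
        values += np.float32(bg)
    else:
        values = np.full((*shape, n_frames), bg, dtype=np.float32)
    values[box] += (
        ((peak_tbr - 1.0) * bg * excess)[..., None] * g[None, None, None, :]
    ).astype(np.float32)
    values = np.clip(values, 0.0, None, out=values).astype(np.float64)
    lesion = np.zeros(shape, dtype=bool)
    lesion[box] = lesion_box

    series = DynamicPETSeries(values=values, voxel_size=spacing, schedule=schedule)
    gt = GroundTruth(
        patient_id=patient_id,
        label=kinetics.label,
        true_peak_tbr=peak_tbr,
        ttp_target=ttp_target,
        slope_target=float(slope_eff),
        seed=int(patient_seed),
        lesion_mask=lesion,
        lesion_center_mm=lesion_center,
        bg_center_mm=bg_center,
    )
    return series, gt


def simulate_cohort(
    spec: PhantomSpec,
    ep_kinetics: KineticClassParams | None = None,
    psp_kinetics: KineticClassParams | None = None,
) -> tuple[list[tuple[DynamicPETSeries, GroundTruth]], pd.DataFrame]:
    """Simulate the full cohort (EP patients first, then PSP).

    Per-patient seeds are derived deterministically from ``spec.seed`` so
    cohorts are reproducible and extensible without perturbing earlier
    patients.
    """
    ep_kinetics = ep_kinetics or default_kinetics("EP")
    psp_kinetics = psp_kinetics or default_kinetics("PSP")
    labels = ["EP"] * spec.n_ep + ["PSP"] * spec.n_psp
    patients: list[tuple[DynamicPETSeries, GroundTruth]] = []
    records = []
    for idx, label in enumerate(labels):
        kin = ep_kinetics if label == "EP" else psp_kinetics
        seed = patient_seed_for(spec.seed, idx)
        pid = f"P{idx + 1:02d}"
        series, gt = simulate_patient(spec, kin, seed, patient_id=pid)
        patients.append((series, gt))
        records.append(
            {
                "patient_id": pid,
                "class": label,
                "true_peak_tbr": gt.true_peak_tbr,
                "seed": seed,
            }
        )
    return patients, pd.DataFrame.from_records(records)
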