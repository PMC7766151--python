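import numpy as np
import pytest

from fetomics.io import fixture_frame
from fetomics.phantom import PhantomSpec, default_kinetics, simulate_cohort, simulate_patient
from fetomics.radiomics import extract_cohort
from fetomics.segmentation import autocontour, background_voi, peak_sphere, sum_window


@pytest.fixture(scope="session")
def cohort_df():
    """The packaged 34-patient clinical table."""
    return fixture_frame()


@pytest.fixture(scope="session")
def noisefree_patient():
    """One noise-free pseudoprogression patient with its segmentation chain."""
    spec = PhantomSpec(noise_sd_per_minute=0.0, seed=11)
    series, gt = simulate_patient(spec, default_kinetics("PSP"), 1234)
    summed = sum_window(series)
    bg = background_voi(summed, gt.bg_center_mm)
    bg_mean = float(summed.values[bg.mask].mean())
    tumor = autocontour(summed, bg_mean)
    peak = peak_sphere(summed, tumor)
    return {
        "series": series,
        "gt": gt,
        "summed": summed,
        "bg": bg,
        "bg_mean": bg_mean,
        "tumor": tumor,
        "peak": peak,
    }


@pytest.fixture(scope="session")
def cohort42_features():
    """Feature table of the default 34-patient cohort at seed 42 (3 VOIs each)."""
    patients, _ = simulate_cohort(PhantomSpec(seed=42))
    return extract_cohort(patients)


def random_texture_instance(rng, max_side=6, max_levels=5):
    """A small random (levels, mask, n_levels) triple for oracle comparisons."""
    shape = tuple(int(s) for s in rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(1, max_levels + 1, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    return levels, mask, int(levels[mask].max())
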