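"""High-pass image filters: Laplacian-of-Gaussian and the undecimated 3D wavelet.

The LoG kernel is built analytically in physical units: the separable
decomposition ``lap(G) = sum_i g''(x_i) prod_{j != i} g(x_j)`` is sampled at
voxel centers, so the impulse response equals the closed-form LoG kernel.
The second-derivative taps are mean-corrected to sum exactly to zero, which
makes the filter annihilate constant images regardless of how coarsely the
kernel is sampled (relevant here: sigma 0.5 mm on 2 mm voxels).

The wavelet stage is a single-level undecimated (stationary) 3D transform
with the coif1 wavelet; the low/high-pass combinations over the three axes
give 8 sub-band images on the same grid as the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["FilterBank", "log_filter", "wavelet_decompose", "WAVELET_BANDS"]

#: sub-band order: letter k is low (L) or high (H) pass along axis k
WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass(frozen=True)
class FilterBank:
    """The 9 filtered images fed to the texture engine: 1 LoG + 8 wavelet bands."""

    log_sigma: float = 0.5  # mm
    wavelet_name: str = "coif1"
    wavelet_level: int = 1

    def apply(
        self, values: np.ndarray, spacing: tuple[float, float, float]
    ) -> dict[str, np.ndarray]:
        out = {f"log-sigma-{self.log_sigma:g}": log_filter(values, spacing, self.log_sigma)}
        bands = wavelet_decompose(values, wavelet=self.wavelet_name)
        for name in WAVELET_BANDS:
            out[f"wavelet-{name}"] = bands[name]
        return out


def _gauss_1d(offsets_mm: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-(offsets_mm**2) / (2 * sigma**2)) / (np.sqrt(2 * np.pi) * sigma)


def _gauss_1d_d2(offsets_mm: np.ndarray, sigma: float) -> np.ndarray:
    g = _gauss_1d(offsets_mm, sigma)
    return g * (offsets_mm**2 - sigma**2) / sigma**4


def log_filter(
    values: np.ndarray, spacing: tuple[float, float, float], sigma_mm: float = 0.5
) -> np.ndarray:
    """Laplacian-of-Gaussian with a physical-unit sigma, on the native grid."""
    values = np.asarray(values, dtype=float)
    axes_1d = []
    for s in spacing:
        radius = max(2, int(np.ceil(6.0 * sigma_mm / s)))
        x = np.arange(-radius, radius + 1) * s
        g = _gauss_1d(x, sigma_mm)
        d2 = _gauss_1d_d2(x, sigma_mm)
        d2 = d2 - d2.mean()  # zero-sum correction: constants map to zero
        axes_1d.append((g, d2))
    kernel = np.zeros([len(g) for g, _ in axes_1d])
    for i in range(3):
        parts = [axes_1d[j][1] if j == i else axes_1d[j][0] for j in range(3)]
        kernel += np.einsum("i,j,k->ijk", *parts)
    return ndimage.convolve(values, kernel, mode="nearest")


def wavelet_decompose(values: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Single-level undecimated 3D wavelet transform; 8 sub-bands, input grid.

    Axes with odd length are edge-padded to even (the stationary transform
    requires even sizes) and the result is cropped back.
    """
    values = np.asarray(values, dtype=float)
    pad = [(0, n % 2) for n in values.shape]
    padded = np.pad(values, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out: dict[str, np.ndarray] = {}
    crop = tuple(slice(0, n) for n in values.shape)
    for key, arr in coeffs.items():
        name = "".join("L" if c == "a" else "H" for c in key)
        out[name] = arr[crop]
    if set(out) != set(WAVELET_BANDS):
        raise RuntimeError(f"unexpected sub-band keys: {sorted(out)}")
    return out
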