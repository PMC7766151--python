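"""The 14 shape descriptors of a VOI.

Surface area and mesh volume come from a marching-cubes triangulation of the
mask (scikit-image); the axis lengths derive from the eigenvalues of the
sample covariance (divisor n-1) of the voxel-center physical coordinates:
``MajorAxisLength = 4 * sqrt(lambda_max)``, the axis convention of the
VOI-enclosing ellipsoid.  Maximum 2D diameters are measured between boundary
voxel centers within planes of constant z (Slice), y (Column) and x (Row).
Degenerate masks (a single voxel, or collinear voxels) report 0 for the
undefined axis features with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = ["shape_features", "SHAPE_NAMES"]

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _mesh(mask: np.ndarray, spacing) -> tuple[float, float]:
    """(mesh volume, surface area) from a marching-cubes triangulation."""
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(abs(signed.sum())), area


def _max_pairwise(coords: np.ndarray) -> float:
    if coords.shape[0] < 2:
        return 0.0
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def _boundary_coords(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    boundary = mask & ~eroded
    return np.argwhere(boundary) * spacing


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    sp = np.asarray(spacing, dtype=float)
    idx = np.argwhere(mask)
    coords = idx * sp
    n = coords.shape[0]
    voxel_volume = float(n * sp.prod())

    if n >= 2:
        # marching cubes needs spatial extent; a single voxel still meshes
        pass
    mesh_volume, surface_area = _mesh(mask, sp)

    out: dict[str, float] = {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else 0.0,
        "Sphericity": (
            (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area
            if surface_area > 0
            else 0.0
        ),
    }

    bcoords = _boundary_coords(mask, sp)
    out["Maximum3DDiameter"] = _max_pairwise(bcoords)
    for name, axis in (
        ("Maximum2DDiameterSlice", 2),   # planes of constant z: x-y distances
        ("Maximum2DDiameterColumn", 1),  # planes of constant y: x-z distances
        ("Maximum2DDiameterRow", 0),     # planes of constant x: y-z distances
    ):
        keep = [a for a in range(3) if a != axis]
        best = 0.0
        for plane in np.unique(bcoords[:, axis]):
            pts = bcoords[np.isclose(bcoords[:, axis], plane)][:, keep]
            best = max(best, _max_pairwise(pts))
        out[name] = best

    if n < 2:
        warnings.warn("single-voxel mask: axis shape features are undefined, reported as 0")
        eigvals = np.zeros(3)
    else:
        cov = np.cov(coords.T, ddof=1)
        eigvals = np.sort(np.clip(np.linalg.eigvalsh(cov), 0.0, None))[::-1]
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
    out["MajorAxisLength"] = major
    out["MinorAxisLength"] = minor
    out["LeastAxisLength"] = least
    if eigvals[0] > 0:
        out["Elongation"] = float(np.sqrt(eigvals[1] / eigvals[0]))
        out["Flatness"] = float(np.sqrt(eigvals[2] / eigvals[0]))
    else:
        warnings.warn("degenerate mask: elongation/flatness undefined, reported as 0")
        out["Elongation"] = 0.0
        out["Flatness"] = 0.0
    return out
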