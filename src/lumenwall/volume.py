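"""3-D scalar volumes with continuous world-coordinate sampling.

A :class:`Volume` wraps a scalar grid together with its physical geometry
(anisotropic spacing in mm, world origin, orthonormal direction matrix) and
exposes trilinear intensity sampling and Gaussian-smoothed gradient sampling
at arbitrary world points.  Every other stage of the pipeline — the particle
tracker, the speed field, the cross-sectional wall model — samples the image
exclusively through this interface, always in world millimetres.

Out-of-bounds samples return NaN, a sentinel distinguishable from any stored
intensity; callers decide the policy (the tracker treats it as "no wall
detected", the wall model as zero potential).
"""

from __future__ import annotations

import dataclasses
import os
from typing import Optional

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "Volume",
    "load_volume",
    "save_volume",
    "sample_intensity",
    "sample_gradient",
]

_ORTHO_TOL = 1e-9


@dataclasses.dataclass
class Volume:
    """Scalar image grid with world geometry.

    Parameters
    ----------
    data
        3-D array indexed ``[i, j, k]``; axis order matches the direction
        matrix columns.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World position (mm) of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal matrix whose columns are the world directions of the
        three array axes (honoured everywhere, not assumed identity).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3, 3)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if not np.all(self.spacing > 0):
            raise ValueError("spacing must be strictly positive on all axes")
        if abs(abs(np.linalg.det(self.direction)) - 1.0) > _ORTHO_TOL or not np.allclose(
            self.direction.T @ self.direction, np.eye(3), atol=1e-9
        ):
            raise ValueError("direction matrix must be orthonormal")
        self._grad_cache: dict = {}

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def min_spacing(self) -> float:
        return float(self.spacing.min())

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to continuous voxel indices."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        local = (p - self.origin) @ self.direction  # D^T (p - o), row-wise
        return local / self.spacing

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        i = np.atleast_2d(np.asarray(idx, dtype=np.float64))
        return (i * self.spacing) @ self.direction.T + self.origin

    def voxel_grid_world(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape ``(*shape, 3)``."""
        nx, ny, nz = self.data.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.voxel_to_world(idx).reshape(nx, ny, nz, 3)

    def contains(self, points: np.ndarray, margin_voxels: float = 0.0) -> np.ndarray:
        v = self.world_to_voxel(points)
        lo = margin_voxels
        hi = np.array(self.data.shape) - 1 - margin_voxels
        return np.all((v >= lo) & (v <= hi), axis=-1)

    # -- sampling ---------------------------------------------------------

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear intensity at world points; NaN outside the grid."""
        pts = np.asarray(points, dtype=np.float64)
        single = pts.ndim == 1
        v = self.world_to_voxel(pts)
        inside = np.all((v >= 0) & (v <= np.array(self.data.shape) - 1), axis=-1)
        out = np.full(v.shape[0], np.nan)
        if np.any(inside):
            coords = v[inside].T
            out[inside] = ndimage.map_coordinates(
                self.data, coords, order=1, mode="nearest"
            )
        return out[0] if single else out

    def _gradient_grids(self, smooth_sigma_mm: float):
        key = round(float(smooth_sigma_mm), 9)
        if key not in self._grad_cache:
            if smooth_sigma_mm > 0:
                sig_vox = smooth_sigma_mm / self.spacing
                sm = ndimage.gaussian_filter(self.data, sigma=sig_vox, mode="nearest")
            else:
                sm = self.data
            self._grad_cache[key] = np.gradient(sm, *self.spacing)
        return self._grad_cache[key]

    def sample_gradient(
        self, points: np.ndarray, smooth_sigma_mm: Optional[float] = None
    ) -> np.ndarray:
        """World-space intensity gradient (per mm) at world points.

        The grid is optionally pre-smoothed with an isotropic Gaussian of
        ``smooth_sigma_mm`` (default half the smallest voxel size), the
        per-axis gradient taken by central differences, sampled trilinearly,
        and rotated into world axes by the direction matrix.  Points within
        one voxel of the border (where central differences lack support)
        return NaN.
        """
        if smooth_sigma_mm is None:
            smooth_sigma_mm = 0.5 * self.min_spacing
        pts = np.asarray(points, dtype=np.float64)
        single = pts.ndim == 1
        v = self.world_to_voxel(pts)
        hi = np.array(self.data.shape) - 2.0
        inside = np.all((v >= 1.0) & (v <= hi), axis=-1)
        out = np.full((v.shape[0], 3), np.nan)
        if np.any(inside):
            grids = self._gradient_grids(smooth_sigma_mm)
            coords = v[inside].T
            g_axis = np.stack(
                [
                    ndimage.map_coordinates(g, coords, order=1, mode="nearest")
                    for g in grids
                ],
                axis=-1,
            )
            out[inside] = g_axis @ self.direction.T
        return out[0] if single else out


# -- spec-level free functions -------------------------------------------


def sample_intensity(vol: Volume, p: np.ndarray) -> np.ndarray:
    """Trilinear intensity at world point(s) ``p``; NaN when outside."""
    return vol.sample(p)


def sample_gradient(
    vol: Volume, p: np.ndarray, smooth_sigma_mm: Optional[float] = None
) -> np.ndarray:
    """Smoothed world-space gradient (per mm) at world point(s) ``p``."""
    return vol.sample_gradient(p, smooth_sigma_mm=smooth_sigma_mm)


# -- I/O -------------------------------------------------------------------


def load_volume(path: str) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    lower = str(path).lower()
    if lower.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        affine = img.affine
        m = affine[:3, :3]
        spacing = np.linalg.norm(m, axis=0)
        direction = m / spacing
        return Volume(data, spacing, affine[:3, 3], direction)
    if lower.endswith((".mha", ".mhd")):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
        spacing = np.array(img.GetSpacing())
        origin = np.array(img.GetOrigin())
        direction = np.array(img.GetDirection()).reshape(3, 3)
        return Volume(data, spacing, origin, direction)
    raise ValueError(f"unsupported volume format: {path}")


def save_volume(vol: Volume, path: str) -> None:
    """Write a NIfTI or MetaImage volume, preserving geometry."""
    lower = str(path).lower()
    if lower.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        affine[:3, :3] = vol.direction * vol.spacing
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.data, affine), str(path))
        return
    if lower.endswith((".mha", ".mhd")):
        img = sitk.GetImageFromArray(vol.data.transpose(2, 1, 0))
        img.SetSpacing(tuple(vol.spacing))
        img.SetOrigin(tuple(vol.origin))
        img.SetDirection(tuple(vol.direction.ravel()))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path}")
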