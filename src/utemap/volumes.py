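"""Voxel-grid containers and NIfTI I/O.

All volumes in one analysis share a grid by contract (the simulator emits
aligned volumes; independently acquired scans must be coregistered upstream).
Axis order is (x, y, z) with 0-based indices; the affine is preserved on
read/write but never interpreted.

Invalid voxels are represented by an explicit boolean mask in memory and by
NaN on disk.  Every statistic computed downstream excludes invalid voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelVolume",
    "VolumeSet",
    "FormatError",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "background_mask",
    "apply_mask",
]


class FormatError(ValueError):
    """Raised when a file does not hold a single 3D scalar image."""


class GridMismatchError(ValueError):
    """Raised when an operation combines volumes on different grids."""


@dataclass
class VoxelVolume:
    """A 3D scalar grid with voxel spacing and an optional validity mask.

    Parameters
    ----------
    data:
        3D array of signal (arbitrary units) or parameter values
        (ms / degrees / dimensionless).
    spacing:
        Per-axis voxel size in mm, strictly positive.
    mask:
        Optional per-voxel validity flag; ``None`` means all voxels valid.
        NaN data voxels are treated as invalid regardless of the mask.
    affine:
        Optional 4x4 world matrix, carried through I/O untouched.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray | None = None
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"volume data must be 3D, got {self.data.ndim}D with shape "
                f"{self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise FormatError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data shape")

    # -- grid -------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "VoxelVolume", rtol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=rtol
        )

    def require_same_grid(self, other: "VoxelVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )

    # -- validity ---------------------------------------------------------
    @property
    def valid(self) -> np.ndarray:
        """Boolean array of voxels that participate in statistics."""
        ok = np.ones(self.shape, dtype=bool) if self.mask is None else self.mask.copy()
        if np.issubdtype(self.data.dtype, np.floating):
            ok &= np.isfinite(self.data)
        return ok

    @property
    def valid_values(self) -> np.ndarray:
        return self.data[self.valid]

    def with_data(
        self, data: np.ndarray, mask: np.ndarray | None = None
    ) -> "VoxelVolume":
        """A new volume on this grid with different data (and optional mask)."""
        return replace(self, data=data, mask=mask)

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(
            self.data.copy(),
            self.spacing,
            None if self.mask is None else self.mask.copy(),
            None if self.affine is None else self.affine.copy(),
        )


@dataclass
class VolumeSet(Mapping[str, VoxelVolume]):
    """Named collection of volumes sharing one grid (e.g. {S1, S2, S3, B1})."""

    volumes: dict[str, VoxelVolume]

    def __post_init__(self) -> None:
        vols = list(self.volumes.values())
        for v in vols[1:]:
            vols[0].require_same_grid(v)

    def __getitem__(self, key: str) -> VoxelVolume:
        return self.volumes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.volumes)

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def grid(self) -> VoxelVolume:
        return next(iter(self.volumes.values()))


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a single-3D-image NIfTI file.

    4D files with a singleton last dimension are squeezed.  NaN voxels are
    converted into the in-memory validity mask.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D image, got {data.ndim} dimensions "
            f"(shape {data.shape})"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = None
    if not np.all(np.isfinite(data)):
        mask = np.isfinite(data)
    return VoxelVolume(data, spacing, mask=mask, affine=np.asarray(img.affine))


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume as float32 NIfTI; invalid voxels are stored as NaN."""
    out = np.asarray(vol.data, dtype=np.float32).copy()
    out[~vol.valid] = np.nan
    affine = vol.affine
    if affine is None:
        affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(out, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def background_mask(vol: VoxelVolume, rel_threshold: float = 0.1) -> VoxelVolume:
    """Foreground mask: voxels at or above ``rel_threshold`` x robust maximum.

    The robust maximum is the 99th percentile of the valid voxels, which
    resists isolated hot pixels.  Returns a boolean volume on the same grid.
    Idempotent: masking an already-masked signal volume changes nothing.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError(f"rel_threshold must lie in (0, 1), got {rel_threshold}")
    valid = vol.valid
    fg = np.zeros(vol.shape, dtype=bool)
    vals = vol.data[valid]
    robust_max = np.percentile(vals, 99) if vals.size else 0.0
    if robust_max <= 0:
        warnings.warn(
            "background_mask: volume has no positive signal; empty mask",
            stacklevel=2,
        )
        return VoxelVolume(fg, vol.spacing)
    fg[valid] = vol.data[valid] >= rel_threshold * robust_max
    return VoxelVolume(fg, vol.spacing)


def apply_mask(vol: VoxelVolume, mask: VoxelVolume | np.ndarray) -> VoxelVolume:
    """Restrict a volume's validity to the intersection with ``mask``."""
    m = mask.data if isinstance(mask, VoxelVolume) else np.asarray(mask)
    if m.shape != vol.shape:
        raise GridMismatchError("mask shape does not match volume shape")
    return vol.with_data(vol.data, mask=vol.valid & m.astype(bool))
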