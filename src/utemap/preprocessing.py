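"""Image conditioning ahead of mapping.

Covers the chain applied between acquisition and parameter estimation:
resampling the low-resolution B1+ map onto the imaging grid, polynomial
smoothing of that map (transmit fields are spatially smooth; voxel noise in
the map would otherwise propagate into flip-angle correction), optional
nonlocal-means denoising of the magnitude images, and subtraction images
(S2 - S3) that highlight fast-relaxing structures.

Volumes are assumed to sit in one frame (the simulator guarantees this;
independently acquired scans must be coregistered upstream) —
:func:`check_alignment` warns when a residual rigid shift is detectable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.restoration import denoise_nl_means, estimate_sigma

from .volumes import GridMismatchError, VoxelVolume

__all__ = [
    "PolynomialField",
    "resample_to_grid",
    "fit_smooth_field",
    "smooth_field_volume",
    "denoise",
    "subtraction_image",
    "check_alignment",
]

_RAYLEIGH_SD = math.sqrt((4.0 - math.pi) / 2.0)  # background sd per channel sigma


def _monomial_exponents(degree: int) -> list[tuple[int, int, int]]:
    return [
        (i, j, k)
        for i, j, k in itertools.product(range(degree + 1), repeat=3)
        if i + j + k <= degree
    ]


def _normalized_coords(shape: tuple[int, int, int]) -> list[np.ndarray]:
    """Per-axis voxel-center coordinates mapped onto [-1, 1] (0 for size-1 axes)."""
    axes = []
    for n in shape:
        axes.append(np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1))
    return list(np.meshgrid(*axes, indexing="ij"))


@dataclass(frozen=True)
class PolynomialField:
    """Trivariate polynomial over normalized [-1,1]^3 grid coordinates.

    Coordinates are normalized for numerical conditioning of the fit; a field
    is therefore tied to a grid shape only through that normalization and can
    be evaluated on any grid.
    """

    degree: int
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be nonnegative")
        n_expected = len(_monomial_exponents(self.degree))
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        if self.coefficients.size != n_expected:
            raise ValueError(
                f"degree {self.degree} needs {n_expected} coefficients, "
                f"got {self.coefficients.size}"
            )

    @classmethod
    def constant(cls, value: float) -> "PolynomialField":
        return cls(0, np.array([float(value)]))

    def evaluate(self, shape: tuple[int, int, int]) -> np.ndarray:
        x, y, z = _normalized_coords(shape)
        out = np.zeros(shape, dtype=float)
        for c, (i, j, k) in zip(self.coefficients, _monomial_exponents(self.degree)):
            out += c * x**i * y**j * z**k
        return out

    def evaluate_on(self, template: VoxelVolume) -> VoxelVolume:
        return VoxelVolume(self.evaluate(template.shape), template.spacing)


def resample_to_grid(lowres: VoxelVolume, target: VoxelVolume) -> VoxelVolume:
    """Trilinear resampling of a low-resolution volume onto a target grid.

    The two volumes are assumed to share a frame with coincident field-of-view
    centers; voxel centers are mapped through mm coordinates relative to the
    grid center.  Coordinates outside the source take the nearest inside
    value.  A degenerate (single-voxel) source axis degrades to
    nearest-neighbor along that axis, with a warning.
    """
    if any(n == 1 for n in lowres.shape):
        warnings.warn(
            "resample_to_grid: source has a single-voxel axis; using "
            "nearest-inside values along it",
            stacklevel=2,
        )
    coords = []
    for ax in range(3):
        idx = np.arange(target.shape[ax], dtype=float)
        mm = (idx - (target.shape[ax] - 1) / 2.0) * target.spacing[ax]
        coords.append(mm / lowres.spacing[ax] + (lowres.shape[ax] - 1) / 2.0)
    grid = np.meshgrid(*coords, indexing="ij")
    data = ndimage.map_coordinates(
        lowres.data, np.array(grid), order=1, mode="nearest"
    )
    return VoxelVolume(data, target.spacing)


def fit_smooth_field(vol: VoxelVolume, degree: int = 3) -> PolynomialField:
    """Least-squares polynomial fit to a volume's valid voxels.

    If the valid voxels cannot support the requested degree (too few, or a
    rank-deficient design), the degree is reduced with a warning.
    """
    if degree < 0:
        raise ValueError("degree must be nonnegative")
    valid = vol.valid
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("cannot fit a field with zero valid voxels")
    x, y, z = (c[valid] for c in _normalized_coords(vol.shape))
    target = vol.data[valid].astype(float)
    deg = degree
    while deg > 0 and n_valid < len(_monomial_exponents(deg)):
        deg -= 1
    while True:
        exps = _monomial_exponents(deg)
        design = np.stack([x**i * y**j * z**k for i, j, k in exps], axis=1)
        coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
        if rank == len(exps) or deg == 0:
            break
        deg -= 1
    if deg != degree:
        warnings.warn(
            f"fit_smooth_field: degree reduced from {degree} to {deg} "
            f"({n_valid} valid voxels)",
            stacklevel=2,
        )
    return PolynomialField(deg, coef)


def smooth_field_volume(vol: VoxelVolume, degree: int = 3) -> VoxelVolume:
    """Fit-and-evaluate convenience: the polynomially smoothed volume.

    The smoothed field is defined on the whole grid (polynomials extrapolate),
    so the result carries no mask.  Applying this to its own output returns
    the same field (a projection).
    """
    return fit_smooth_field(vol, degree).evaluate_on(vol)


def denoise(vol: VoxelVolume, strength: float = 1.0) -> VoxelVolume:
    """Patchwise nonlocal-means denoising of a magnitude volume.

    The channel noise level is estimated from the background (voxels outside
    the validity mask, whose magnitude is Rayleigh-distributed) when a mask
    is present, and by wavelet estimation otherwise.  ``strength`` scales the
    filtering parameter h; ``strength=0`` is the identity.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if strength == 0:
        return vol.copy()
    if vol.mask is not None and np.any(~vol.mask):
        bg = vol.data[~vol.mask & np.isfinite(vol.data)]
        sigma = float(np.std(bg)) / _RAYLEIGH_SD if bg.size else 0.0
    else:
        sigma = float(estimate_sigma(np.nan_to_num(vol.data)))
    if sigma == 0:
        return vol.copy()
    filled = np.nan_to_num(vol.data, nan=0.0)
    out = denoise_nl_means(
        filled,
        patch_size=3,
        patch_distance=5,
        h=1.15 * sigma * strength,
        sigma=sigma,
        fast_mode=True,
    )
    out = np.asarray(out, dtype=float)
    out[~vol.valid] = np.nan
    return VoxelVolume(out, vol.spacing, mask=None if vol.mask is None else vol.mask.copy())


def subtraction_image(s2: VoxelVolume, s3: VoxelVolume) -> VoxelVolume:
    """S2 - S3: contrast that highlights fast-relaxing structures.

    At equal proton density, short-T2* tissue loses more signal between the
    two echoes and appears bright.  Negative values are retained.
    """
    s2.require_same_grid(s3)
    valid = s2.valid & s3.valid
    data = np.where(valid, s2.data - s3.data, np.nan)
    return VoxelVolume(data, s2.spacing, mask=valid)


def check_alignment(
    a: VoxelVolume, b: VoxelVolume, tol_voxels: float = 0.5
) -> np.ndarray:
    """Estimate the rigid shift between two volumes; warn when it exceeds tol.

    A cross-correlation shift check only — not a registration.  Volumes are
    expected to be aligned by construction; a detectable shift means the
    shared-frame contract is broken upstream.
    """
    if a.shape != b.shape:
        raise GridMismatchError("alignment check requires equal shapes")
    shift, _, _ = phase_cross_correlation(
        np.nan_to_num(a.data), np.nan_to_num(b.data), upsample_factor=10
    )
    if np.linalg.norm(shift) > tol_voxels:
        warnings.warn(
            f"check_alignment: detected shift {shift} voxels exceeds "
            f"{tol_voxels}; volumes are not aligned",
            stacklevel=2,
        )
    return np.asarray(shift)
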