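"""VOI extraction and agreement statistics.

Validation mirrors common relaxometry practice: cylindrical volumes of
interest eroded inward from each tube wall (partial-volume voxels at the
wall would otherwise contaminate the statistics), per-VOI mean/SD/CV, and
Bland-Altman agreement between a mapping method and its reference, with
limits of agreement at mean difference +/- 1.96 SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .volumes import VolumeSet, VoxelVolume

__all__ = [
    "VOI",
    "VoiStats",
    "AgreementReport",
    "EmptyVOIError",
    "tube_vois",
    "split_voi_slabs",
    "voi_stats",
    "bland_altman",
]

MIN_REPORTABLE_VOXELS = 100
"""Conventional floor for reportable in-vivo-style VOIs (configurable)."""


class EmptyVOIError(ValueError):
    """Raised when a VOI contains no valid voxels of the queried map."""


@dataclass
class VOI:
    """A labelled voxel index set on a named grid (stored as a boolean mask)."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("VOI mask must be 3D")
        if self.n_voxels < 1:
            raise ValueError(f"VOI '{self.label}' is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def is_reportable(self, floor: int = MIN_REPORTABLE_VOXELS) -> bool:
        return self.n_voxels >= floor


class VoiStats(NamedTuple):
    mean: float
    sd: float
    cv: float
    n_valid: int


@dataclass
class AgreementReport:
    """Bland-Altman agreement: differences are reference - test.

    With ``percent=True`` differences are expressed as a percentage of the
    reference.  Limits of agreement are mean +/- 1.96 SD exactly.
    """

    pairs: list[tuple[float, float]]
    differences: np.ndarray
    mean_difference: float
    sd_difference: float
    percent: bool

    @property
    def loa_low(self) -> float:
        return self.mean_difference - 1.96 * self.sd_difference

    @property
    def loa_high(self) -> float:
        return self.mean_difference + 1.96 * self.sd_difference

    @property
    def n(self) -> int:
        return len(self.pairs)


def _erode_in_plane(mask: np.ndarray, margin: int) -> np.ndarray:
    """Keep voxels whose in-plane distance to the region wall is >= margin.

    Uses the Euclidean distance transform per slice; voxel centers sit half
    a voxel inside the wall, so the threshold is margin + 0.5.  This tracks
    the continuum geometry (a radius-r tube eroded by m keeps radius r - m)
    more faithfully than structuring-element erosion.
    """
    out = np.zeros_like(mask)
    for z in range(mask.shape[2]):
        if mask[:, :, z].any():
            dist = ndimage.distance_transform_edt(mask[:, :, z])
            out[:, :, z] = dist >= margin + 0.5
    return out


def tube_vois(truth: VolumeSet, margin_voxels: int = 3) -> list[VOI]:
    """Per-tube cylindrical VOIs eroded in-plane by ``margin_voxels``.

    Works from the simulator's integer label map.  A tube that erodes to
    nothing (margin exceeding its radius) is flagged with a warning and
    skipped.
    """
    if margin_voxels < 0:
        raise ValueError("margin_voxels must be >= 0")
    label = truth["label"].data.astype(int)
    vois = []
    for tube_id in range(1, label.max() + 1):
        mask = label == tube_id
        if margin_voxels > 0:
            mask = _erode_in_plane(mask, margin_voxels)
        if not np.any(mask):
            warnings.warn(
                f"tube {tube_id}: erosion by {margin_voxels} voxels emptied the "
                "VOI; tube skipped",
                stacklevel=2,
            )
            continue
        vois.append(VOI(f"tube{tube_id}", mask))
    return vois


def split_voi_slabs(voi: VOI, n: int = 2) -> list[VOI]:
    """Split a VOI into ``n`` slabs along z (e.g. two sub-VOIs per tube, so
    the unit of agreement analysis matches a two-VOIs-per-tube design)."""
    zs = np.unique(np.nonzero(voi.mask)[2])
    out = []
    for i, chunk in enumerate(np.array_split(zs, n)):
        if chunk.size == 0:
            continue
        m = np.zeros_like(voi.mask)
        m[:, :, chunk] = voi.mask[:, :, chunk]
        out.append(VOI(f"{voi.label}_s{i}", m))
    return out


def voi_stats(map_vol: VoxelVolume, voi: VOI) -> VoiStats:
    """Mean/SD/CV over the VOI's valid voxels (invalid voxels excluded)."""
    if voi.mask.shape != map_vol.shape:
        raise ValueError("VOI is not defined on the map's grid")
    sel = voi.mask & map_vol.valid
    n = int(sel.sum())
    if n == 0:
        raise EmptyVOIError(f"VOI '{voi.label}' has no valid voxels")
    vals = map_vol.data[sel]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    cv = sd / mean if mean != 0 else float("nan")
    return VoiStats(mean, sd, cv, n)


def bland_altman(
    pairs: Sequence[tuple[float, float]], percent: bool = True
) -> AgreementReport:
    """Bland-Altman agreement over (reference, test) pairs.

    Differences are reference - test, as percent of reference when
    ``percent`` (the default, since agreement in relaxometry phantom work is
    conventionally reported in percent).  Zero-reference pairs cannot be
    expressed in percent and are excluded with a warning.  Swapping the
    roles of reference and test negates the mean difference and mirrors the
    limits of agreement.
    """
    kept = list(pairs)
    if percent:
        dropped = [p for p in kept if p[0] == 0]
        if dropped:
            warnings.warn(
                f"bland_altman: excluded {len(dropped)} pair(s) with zero "
                "reference (percent difference undefined)",
                stacklevel=2,
            )
        kept = [p for p in kept if p[0] != 0]
    if len(kept) < 2:
        raise ValueError("need at least 2 usable pairs")
    ref = np.array([p[0] for p in kept], dtype=float)
    test = np.array([p[1] for p in kept], dtype=float)
    diff = ref - test
    if percent:
        diff = 100.0 * diff / ref
    return AgreementReport(
        pairs=kept,
        differences=diff,
        mean_difference=float(diff.mean()),
        sd_difference=float(diff.std(ddof=1)),
        percent=percent,
    )
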