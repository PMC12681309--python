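"""Lookup-table T1 estimation with B1+ correction, and the IR reference fit.

The S1/S2 ratio of two SPGR scans with different flip angle and TR is a
strictly monotone function of T1 (for a sensible protocol pair), so T1 can
be read off a precomputed table of predicted ratios over a dense T1 grid
(default 1-4000 ms in 1 ms steps).  Transmit-field inhomogeneity changes
the effective flip angles; a bank of tables indexed by the integer effective
angle of the second scan, together with a relative B1+ map, selects the
matching table per voxel.

The reference method is inversion-recovery fitting of magnitude data with
the three-parameter model |A - B exp(-TI/T1)|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares

from .signal_models import AcquisitionProtocol, signal_ratio
from .volumes import VoxelVolume

__all__ = [
    "LookupTable",
    "LutBank",
    "InversionSeries",
    "LutBuildError",
    "build_lut",
    "lut_invert",
    "build_lut_bank",
    "map_t1",
    "ir_fit",
    "IRFitResult",
    "T1MapResult",
]

DEFAULT_T1_GRID = np.arange(1.0, 4001.0)
"""Default table grid: 1-4000 ms in 1 ms steps."""


class LutBuildError(ValueError):
    """Raised when a protocol pair yields a non-monotone ratio curve."""


@dataclass(frozen=True)
class LookupTable:
    """Monotone map from a T1 grid to predicted S1/S2 ratios.

    ``b1_scale`` is the relative transmit scale (1.0 = nominal angles) the
    table assumes; ``increasing`` records the ratio curve's direction.
    """

    t1_grid: np.ndarray
    ratios: np.ndarray
    b1_scale: float
    protocols: tuple[AcquisitionProtocol, AcquisitionProtocol]
    increasing: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "t1_grid", np.asarray(self.t1_grid, dtype=float))
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))
        if self.t1_grid.size != self.ratios.size:
            raise ValueError("t1_grid and ratios must have equal length")
        d = np.diff(self.ratios)
        if np.all(d > 0):
            object.__setattr__(self, "increasing", True)
        elif np.all(d < 0):
            object.__setattr__(self, "increasing", False)
        else:
            p1, p2 = self.protocols
            raise LutBuildError(
                "ratio curve is not strictly monotone in T1 for protocol pair "
                f"({p1.label or p1}, {p2.label or p2}) at b1_scale={self.b1_scale}"
            )

    def __len__(self) -> int:
        return int(self.t1_grid.size)


class LutInversion(NamedTuple):
    t1: float | np.ndarray
    out_of_range: bool | np.ndarray


class T1MapResult(NamedTuple):
    volume: VoxelVolume
    out_of_range: np.ndarray
    n_outside_bank: int


class IRFitResult(NamedTuple):
    a: float
    b: float
    t1: float
    residual: float
    degenerate: bool


def build_lut(
    p1: AcquisitionProtocol,
    p2: AcquisitionProtocol,
    b1_scale: float = 1.0,
    t1_grid: np.ndarray | None = None,
) -> LookupTable:
    """Tabulate the predicted S1/S2 ratio over a T1 grid at one B1+ scale.

    Strict monotonicity is asserted at build time; a non-monotone curve
    (an ill-chosen protocol pair) refuses to build.
    """
    grid = DEFAULT_T1_GRID if t1_grid is None else np.asarray(t1_grid, dtype=float)
    ratios = signal_ratio(grid, p1, p2, b1_scale=b1_scale)
    return LookupTable(grid, ratios, float(b1_scale), (p1, p2))


def lut_invert(ratio, lut: LookupTable, interpolate: bool = False) -> LutInversion:
    """Measured ratio -> grid T1 with the nearest predicted ratio.

    Ties break toward the smaller T1.  Ratios beyond the table's range clamp
    to the boundary T1 and set ``out_of_range``; non-finite ratios yield NaN.
    ``interpolate=True`` returns linearly interpolated (off-grid) T1 instead
    of the nearest grid entry.
    """
    r = np.asarray(ratio, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    ratios = lut.ratios if lut.increasing else lut.ratios[::-1]
    t1s = lut.t1_grid if lut.increasing else lut.t1_grid[::-1]
    finite = np.isfinite(r)
    out_of_range = finite & ((r < ratios[0]) | (r > ratios[-1]))
    t1 = np.full(r.shape, np.nan)
    if np.any(finite):
        rc = np.clip(r[finite], ratios[0], ratios[-1])
        if interpolate:
            t1[finite] = np.interp(rc, ratios, t1s)
        else:
            hi = np.clip(np.searchsorted(ratios, rc), 1, ratios.size - 1)
            lo = hi - 1
            d_lo = np.abs(rc - ratios[lo])
            d_hi = np.abs(ratios[hi] - rc)
            t_lo, t_hi = t1s[lo], t1s[hi]
            # equal distance -> the smaller T1 of the two bracketing entries
            pick_lo = (d_lo < d_hi) | ((d_lo == d_hi) & (t_lo <= t_hi))
            t1[finite] = np.where(pick_lo, t_lo, t_hi)
    if scalar:
        return LutInversion(float(t1[0]), bool(out_of_range[0]))
    return LutInversion(t1, out_of_range)


@dataclass(frozen=True)
class LutBank:
    """Lookup tables indexed by the integer effective flip angle of scan 2.

    Both scans share one transmit chain, so a single B1+ scale multiplies
    FA1 and FA2 jointly; the bank key is round(b1 * FA2) and the table for
    key k is built at b1_scale = k / FA2 (FA1 scaled by the same factor,
    not independently rounded).
    """

    tables: dict[int, LookupTable]
    fa2_nominal: float

    def __post_init__(self) -> None:
        keys = sorted(self.tables)
        if not keys:
            raise ValueError("empty LUT bank")
        if keys != list(range(keys[0], keys[-1] + 1)):
            raise ValueError("LUT bank must cover its angle range without gaps")

    @property
    def coverage(self) -> tuple[int, int]:
        keys = sorted(self.tables)
        return keys[0], keys[-1]


def build_lut_bank(
    p1: AcquisitionProtocol,
    p2: AcquisitionProtocol,
    fa_lo: int = 1,
    fa_hi: int = 179,
    t1_grid: np.ndarray | None = None,
) -> LutBank:
    """One table per integer effective FA2 in [fa_lo, fa_hi].

    The upper default stops at 179 deg: a 180 deg excitation leaves no
    transverse signal, so no ratio exists there.
    """
    tables = {}
    for k in range(fa_lo, fa_hi + 1):
        b1 = k / p2.fa
        tables[k] = build_lut(p1, p2, b1_scale=b1, t1_grid=t1_grid)
    return LutBank(tables, p2.fa)


def map_t1(
    s1: VoxelVolume,
    s2: VoxelVolume,
    b1: VoxelVolume,
    bank: LutBank,
    interpolate: bool = False,
) -> T1MapResult:
    """Voxelwise LUT T1 map from the S1/S2 ratio with B1+ correction.

    Per valid voxel the effective angle round(b1 * FA2) selects the bank
    table and the measured ratio is inverted through it.  Voxels whose
    effective angle falls outside the bank, or with S2 <= 0, are invalid.
    Out-of-range ratios clamp to the boundary T1 and are flagged (the map
    stays visually complete); the flag is returned per voxel.
    """
    s1.require_same_grid(s2)
    s1.require_same_grid(b1)
    valid = s1.valid & s2.valid & b1.valid & (s2.data > 0)
    eff = np.rint(b1.data * bank.fa2_nominal).astype(int)
    lo, hi = bank.coverage
    outside = valid & ((eff < lo) | (eff > hi))
    n_outside = int(outside.sum())
    if n_outside:
        warnings.warn(
            f"map_t1: {n_outside} voxels have effective angles outside the "
            f"LUT bank coverage [{lo}, {hi}] deg and were invalidated",
            stacklevel=2,
        )
    valid &= ~outside
    t1 = np.full(s1.shape, np.nan)
    oor = np.zeros(s1.shape, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, s1.data / s2.data, np.nan)
    for key in np.unique(eff[valid]):
        sel = valid & (eff == key)
        inv = lut_invert(ratio[sel], bank.tables[int(key)], interpolate=interpolate)
        t1[sel] = inv.t1
        oor[sel] = inv.out_of_range
    valid &= np.isfinite(t1)
    return T1MapResult(VoxelVolume(t1, s1.spacing, mask=valid), oor, n_outside)


@dataclass
class InversionSeries:
    """Magnitude signal at a set of inversion times (one recovery curve)."""

    tis: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.tis = np.asarray(self.tis, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.tis.size < 4:
            raise ValueError("need >= 4 inversion times (3 free parameters + 1)")
        if np.any(np.diff(self.tis) <= 0):
            raise ValueError("inversion times must be strictly ascending")
        if self.signals.shape != self.tis.shape:
            raise ValueError("signals must match inversion times in shape")


def ir_fit(
    series: InversionSeries,
    n_starts: int = 16,
    t1_start_range: tuple[float, float] = (10.0, 8000.0),
) -> IRFitResult:
    """Three-parameter magnitude IR fit: |A - B exp(-TI/T1)|.

    Magnitude (not signed) model, because UTE magnitude images carry no
    polarity; no polarity restoration is attempted.  Nonlinear least squares
    is multi-started over a log-spaced T1 grid and the lowest-residual
    solution is kept.  ``degenerate`` flags fits with no recovery contrast
    (B ~ 0) or T1 pinned at the search bounds.
    """
    y = series.signals
    a0 = float(np.max(y))
    if a0 <= 0:
        raise ValueError("inversion series has no positive signal")
    lo, hi = (1e-2, 1e5)

    def resid(p: np.ndarray) -> np.ndarray:
        a, b, t1 = p
        return np.abs(a - b * np.exp(-series.tis / t1)) - y

    best = None
    for t1_0 in np.geomspace(*t1_start_range, n_starts):
        try:
            sol = least_squares(
                resid,
                x0=np.array([a0, 2 * a0, t1_0]),
                bounds=([0.0, 0.0, lo], [np.inf, np.inf, hi]),
                method="trf",
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("IR fit failed to converge from every start")
    a, b, t1 = best.x
    # degenerate when there is no recovery contrast, T1 sits at the search
    # bounds, or the inversion decays entirely before the first sample
    degenerate = (
        (b < 1e-6 * max(a, 1e-30)) or t1 < 2 * lo or t1 > hi / 2 or t1 < series.tis[0]
    )
    return IRFitResult(
        float(a), float(b), float(t1), float(np.sqrt(2 * best.cost)), bool(degenerate)
    )
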