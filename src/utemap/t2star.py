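"""Voxelwise T2* estimation.

Three estimators are provided:

* :func:`dual_echo_t2star` — closed-form two-echo estimate
  T2* = (TE3 - TE2) / ln(S2/S3), the fast mapping method.
* :func:`multi_echo_t2star` / :func:`monoexp_fit` — mono-exponential
  least-squares fit over >= 3 echoes (the conventional "3TE" method).
* :func:`etsme_reference` — fit over an echo-train-shifted multi-echo
  (ETsME) series whose densely sampled early echoes anchor fast decays;
  this is the reference method for phantom validation.

Mono-exponential fitting uses log-linear weighted least squares with
weights proportional to the squared signal: deterministic, free of fit
failures, and adequate for 3-26 points.  An optional nonlinear refinement
is available for the reference fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .volumes import VoxelVolume

__all__ = [
    "EchoSeries",
    "RelaxometryMap",
    "MonoExpFit",
    "dual_echo_t2star",
    "monoexp_fit",
    "multi_echo_t2star",
    "etsme_echo_times",
    "etsme_reference",
]

DEFAULT_T2_CAP = 100.0
"""Upper cap (ms) for T2* estimates; longer values are clipped and flagged."""


@dataclass
class EchoSeries:
    """Magnitude samples at a set of echo times (one decay curve)."""

    tes: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.tes = np.asarray(self.tes, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.tes.ndim != 1 or self.tes.size < 2:
            raise ValueError("need at least two echo times")
        if np.any(np.diff(self.tes) <= 0):
            raise ValueError(f"echo times must be strictly ascending: {self.tes}")
        if self.signals.shape[-1] != self.tes.size:
            raise ValueError("signals last axis must match number of echoes")


class RelaxometryMap(NamedTuple):
    """A parameter map plus the per-voxel cap-clipping flag."""

    volume: VoxelVolume
    clipped: np.ndarray


class MonoExpFit(NamedTuple):
    s0: float
    t2star: float
    residual: float


def _loglinear_fit(
    tes: np.ndarray, signals: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted LS of ln S = ln S0 - TE/T2* along the last axis.

    Returns (s0, t2star); t2star is +inf where the fitted slope is >= 0.
    Accepts stacked voxel data: ``signals`` and ``weights`` shaped
    (..., n_echo).  Two-point input reduces to the exact line through both
    samples, which is what the dual-echo formula computes.
    """
    y = np.log(signals)
    x = tes
    sw = weights.sum(axis=-1)
    mx = (weights * x).sum(axis=-1) / sw
    my = (weights * y).sum(axis=-1) / sw
    cov = (weights * (x - mx[..., None]) * (y - my[..., None])).sum(axis=-1)
    var = (weights * (x - mx[..., None]) ** 2).sum(axis=-1)
    slope = cov / var
    s0 = np.exp(my - slope * mx)
    with np.errstate(divide="ignore"):
        t2star = np.where(slope < 0, -1.0 / slope, np.inf)
    return s0, t2star


def dual_echo_t2star(
    s2: VoxelVolume,
    s3: VoxelVolume,
    te2: float,
    te3: float,
    t2_cap: float = DEFAULT_T2_CAP,
) -> RelaxometryMap:
    """Closed-form dual-echo T2* map: (TE3 - TE2) / ln(S2/S3).

    Voxels with S3 <= 0 or S2 <= S3 (non-decaying, implying infinite or
    negative T2*) are marked invalid.  Estimates above ``t2_cap`` are clipped
    to the cap and flagged in ``clipped``; they remain in the map so that
    region statistics may include or exclude them explicitly.
    """
    if not te3 > te2 >= 0:
        raise ValueError(f"need TE3 > TE2 >= 0, got TE2={te2}, TE3={te3}")
    s2.require_same_grid(s3)
    with np.errstate(divide="ignore", invalid="ignore"):
        valid = s2.valid & s3.valid & (s3.data > 0) & (s2.data > s3.data)
        t2 = np.full(s2.shape, np.nan)
        t2[valid] = (te3 - te2) / np.log(s2.data[valid] / s3.data[valid])
    clipped = valid & (t2 > t2_cap)
    t2[clipped] = t2_cap
    return RelaxometryMap(VoxelVolume(t2, s2.spacing, mask=valid), clipped)


def monoexp_fit(series: EchoSeries, refine: bool = False) -> MonoExpFit:
    """Mono-exponential fit S(TE) = S0 exp(-TE/T2*) to one decay curve.

    Requires at least three positive samples; non-positive samples (possible
    after denoising or at the noise floor) are excluded rather than clamped,
    to avoid fabricating long decay constants.  ``refine=True`` runs a
    nonlinear least-squares polish started from the log-linear solution.
    """
    if series.signals.ndim != 1:
        raise ValueError("monoexp_fit expects a single decay curve")
    keep = series.signals > 0
    tes, sig = series.tes[keep], series.signals[keep]
    if tes.size < 3:
        raise ValueError(
            f"need >= 3 positive samples for a mono-exponential fit, got {tes.size}"
        )
    s0, t2 = _loglinear_fit(tes, sig, sig**2)
    s0, t2 = float(s0), float(t2)
    if refine and np.isfinite(t2):
        try:
            popt, _ = curve_fit(
                lambda te, a, t: a * np.exp(-te / t),
                tes,
                sig,
                p0=(s0, t2),
                maxfev=2000,
            )
            s0, t2 = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass  # keep the log-linear solution
    resid = float(np.linalg.norm(sig - s0 * np.exp(-tes / t2))) if np.isfinite(t2) else np.inf
    return MonoExpFit(s0, t2, resid)


def multi_echo_t2star(
    echoes: Sequence[VoxelVolume],
    tes: Sequence[float],
    t2_cap: float = DEFAULT_T2_CAP,
) -> RelaxometryMap:
    """Voxelwise mono-exponential T2* fit over >= 3 echo volumes."""
    if len(echoes) != len(tes):
        raise ValueError("one echo time per volume required")
    if len(echoes) < 3:
        raise ValueError("need >= 3 echoes; use dual_echo_t2star for two")
    ref = echoes[0]
    for v in echoes[1:]:
        ref.require_same_grid(v)
    te_arr = np.asarray(tes, dtype=float)
    if np.any(np.diff(te_arr) <= 0):
        raise ValueError("echo times must be strictly ascending")
    stack = np.stack([v.data for v in echoes], axis=-1)
    valid = np.all([v.valid for v in echoes], axis=0) & np.all(stack > 0, axis=-1)
    t2 = np.full(ref.shape, np.nan)
    if np.any(valid):
        sig = stack[valid]
        _, fit = _loglinear_fit(te_arr, sig, sig**2)
        t2[valid] = fit
    finite = valid & np.isfinite(t2)
    valid = finite
    clipped = valid & (t2 > t2_cap)
    t2[clipped] = t2_cap
    t2[~valid] = np.nan
    return RelaxometryMap(VoxelVolume(t2, ref.spacing, mask=valid), clipped)


def etsme_echo_times(
    n_shift: int = 22,
    shift_lo: float = 0.03,
    shift_hi: float = 1.5,
    fixed: Sequence[float] = (4.92, 7.38, 9.84, 12.3),
) -> np.ndarray:
    """TE samples of the echo-train-shifted multi-echo reference acquisition.

    ``n_shift`` repetitions slide the first echo from ``shift_lo`` to
    ``shift_hi`` ms while later echoes stay fixed; pooling all repetitions
    yields a decay curve with dense early sampling.
    """
    shifted = np.linspace(shift_lo, shift_hi, n_shift)
    return np.unique(np.concatenate([shifted, np.asarray(fixed, dtype=float)]))


def etsme_reference(
    series: EchoSeries,
    shifted_only: bool = False,
    n_shift: int = 22,
    refine: bool = True,
) -> float:
    """Reference T2* from an ETsME series (mono-exponential fit over all TEs).

    ``shifted_only=True`` restricts the fit to the first ``n_shift`` (sliding
    first-echo) samples, dropping the fixed later echoes.

    The reference fit defaults to the nonlinear polish (``refine=True``):
    for fast-decaying samples the fixed late echoes sit on the Rician noise
    floor, and a log-domain weighted fit hands those floor samples enormous
    leverage (the log transform stretches small magnitudes), inflating the
    reference by tens of percent.  The nonlinear fit weights residuals on
    the signal scale and is insensitive to the floor.
    """
    if shifted_only:
        series = EchoSeries(series.tes[:n_shift], series.signals[..., :n_shift])
    return monoexp_fit(series, refine=refine).t2star
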