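"""Digital multi-tube relaxometry phantoms and scan simulation.

Two default phantoms mirror the classic validation setup for fast
musculoskeletal relaxometry: a seven-tube phantom spanning T2* = 1-20 ms
(fast-decaying gels) and a ten-tube phantom spanning T1 = 300-1300 ms.
Ground truth is specified directly as per-tube (T1, T2*, S0) rather than
through gel chemistry.

Scans are simulated voxelwise from the SPGR steady-state model with the
local effective flip angle b1 * FA, then corrupted with Rician magnitude
noise: magnitude = sqrt((mean + g1)^2 + g2^2) with g ~ N(0, sigma^2).
Rician (two-channel Gaussian) noise matters here — its signal floor is what
biases log-ratio T2* estimators when the later echo decays into the noise,
so Gaussian noise would hide the very effect the echo-time choice controls.

The noise level convention: SNR is quoted against the fully relaxed
(TR >> T1) signal at TE = 0 for the mapping scan's flip angle, i.e.
sigma = s0 * sin(fa) / SNR.  This anchors sigma to the object and transmit
settings rather than to any tube's T1, and one sigma serves every scan of a
session, as a receive-chain property should.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .preprocessing import PolynomialField
from .signal_models import AcquisitionProtocol, TissueParams, spgr_signal
from .volumes import VolumeSet, VoxelVolume

__all__ = [
    "TubeSpec",
    "PhantomSpec",
    "PhantomSpecError",
    "default_t2star_phantom",
    "default_t1_phantom",
    "render_truth",
    "simulate_scan",
    "simulate_ir_series",
    "noise_sigma_for_snr",
]

DEFAULT_SHAPE = (64, 64, 16)
DEFAULT_SPACING = (0.8, 0.8, 0.8)
DEFAULT_S0 = 100.0


class PhantomSpecError(ValueError):
    """Raised for geometrically impossible phantom specifications."""


@dataclass(frozen=True)
class TubeSpec:
    """One cylindrical tube: in-plane center/radius (mm) and ground truth."""

    center_xy: tuple[float, float]
    radius: float
    t1: float
    t2star: float
    s0: float = DEFAULT_S0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("tube radius must be positive")
        if self.t1 <= 0 or self.t2star <= 0 or self.s0 < 0:
            raise ValueError("tube relaxation parameters must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Full simulator state: grid, tubes, B1+ field, noise level, seed.

    Identical spec + seed reproduce identical output bit for bit.
    """

    tubes: tuple[TubeSpec, ...]
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    background_s0: float = 0.0
    b1_field: PolynomialField = field(
        default_factory=lambda: PolynomialField.constant(1.0)
    )
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for i, a in enumerate(self.tubes):
            for b in self.tubes[i + 1 :]:
                d = np.hypot(
                    a.center_xy[0] - b.center_xy[0], a.center_xy[1] - b.center_xy[1]
                )
                if d < a.radius + b.radius:
                    raise PhantomSpecError(
                        f"tubes at {a.center_xy} and {b.center_xy} overlap"
                    )


def _ring_centers(n: int, ring_radius: float) -> list[tuple[float, float]]:
    ang = 2 * np.pi * np.arange(n) / n
    return [
        (float(ring_radius * np.cos(a)), float(ring_radius * np.sin(a))) for a in ang
    ]


def default_t2star_phantom(noise_sigma: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Seven tubes with T2* = {1, 2, 3, 5, 8, 12, 20} ms on a ring.

    The values cover the 1-20 ms range of fast-relaxing musculoskeletal
    tissue with denser sampling at the short end, where echo-time choices
    matter most.  All tubes share T1 = 1000 ms.
    """
    t2stars = [1.0, 2.0, 3.0, 5.0, 8.0, 12.0, 20.0]
    tubes = tuple(
        TubeSpec(c, radius=5.0, t1=1000.0, t2star=t2)
        for c, t2 in zip(_ring_centers(7, 16.0), t2stars)
    )
    return PhantomSpec(tubes, noise_sigma=noise_sigma, seed=seed)


def default_t1_phantom(noise_sigma: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Ten tubes with T1 uniformly spanning 300-1300 ms, common T2* = 30 ms."""
    t1s = np.linspace(300.0, 1300.0, 10)
    tubes = tuple(
        TubeSpec(c, radius=4.2, t1=float(t1), t2star=30.0)
        for c, t1 in zip(_ring_centers(10, 18.0), t1s)
    )
    return PhantomSpec(tubes, noise_sigma=noise_sigma, seed=seed)


def with_b1_inhomogeneity(spec: PhantomSpec, amplitude: float = 0.2) -> PhantomSpec:
    """Replace the B1+ field with a smooth quadratic bowl (1 at center,
    1 - amplitude at the corners), emulating transmit falloff at the FOV edge."""
    # f = 1 - (amplitude/3)(x^2 + y^2 + z^2) on normalized coordinates
    deg2 = PolynomialField(2, np.zeros(10))
    coefs = np.zeros(deg2.coefficients.size)
    from .preprocessing import _monomial_exponents  # stable monomial order

    for idx, e in enumerate(_monomial_exponents(2)):
        if e == (0, 0, 0):
            coefs[idx] = 1.0
        elif e in ((2, 0, 0), (0, 2, 0), (0, 0, 2)):
            coefs[idx] = -amplitude / 3.0
    return replace(spec, b1_field=PolynomialField(2, coefs))


def render_truth(spec: PhantomSpec) -> VolumeSet:
    """Voxelize the phantom: T1/T2*/S0/B1 truth maps plus an integer label map.

    A voxel belongs to a tube when its center falls inside the tube circle.
    T1 and T2* are undefined (masked) outside the tubes; S0 is the background
    level there.  Labels: 0 = background, 1..n = tube index.
    """
    nx, ny, nz = spec.shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * spec.spacing[0]
    y = (np.arange(ny) - (ny - 1) / 2.0) * spec.spacing[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    label2d = np.zeros((nx, ny), dtype=int)
    for i, tube in enumerate(spec.tubes, start=1):
        inside = (xx - tube.center_xy[0]) ** 2 + (yy - tube.center_xy[1]) ** 2 <= (
            tube.radius**2
        )
        if np.any(label2d[inside] > 0):  # pragma: no cover - guarded by spec
            raise PhantomSpecError("overlapping tubes in rendered geometry")
        label2d[inside] = i
    label = np.broadcast_to(label2d[:, :, None], spec.shape).copy()

    t1 = np.full(spec.shape, np.nan)
    t2s = np.full(spec.shape, np.nan)
    s0 = np.full(spec.shape, float(spec.background_s0))
    for i, tube in enumerate(spec.tubes, start=1):
        sel = label == i
        t1[sel] = tube.t1
        t2s[sel] = tube.t2star
        s0[sel] = tube.s0
    in_tube = label > 0
    b1 = spec.b1_field.evaluate(spec.shape)
    sp = spec.spacing
    return VolumeSet(
        {
            "t1": VoxelVolume(t1, sp, mask=in_tube.copy()),
            "t2star": VoxelVolume(t2s, sp, mask=in_tube.copy()),
            "s0": VoxelVolume(s0, sp),
            "b1": VoxelVolume(b1, sp),
            "label": VoxelVolume(label.astype(float), sp),
        }
    )


def _rician(mean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return mean.copy()
    g1 = rng.normal(0.0, sigma, mean.shape)
    g2 = rng.normal(0.0, sigma, mean.shape)
    return np.hypot(mean + g1, g2)


def _noiseless_echo(truth: VolumeSet, protocol: AcquisitionProtocol, te: float) -> np.ndarray:
    t1 = truth["t1"].data
    t2s = truth["t2star"].data
    s0 = truth["s0"].data
    b1 = truth["b1"].data
    in_tube = truth["t1"].valid
    mean = np.zeros(truth.grid.shape)
    if np.any(in_tube):
        tissue = TissueParams(t1[in_tube], t2s[in_tube], s0[in_tube])
        # effective angle varies per voxel through the B1+ field
        a = b1[in_tube] * protocol.fa
        e1 = np.exp(-protocol.tr / tissue.t1)
        ar = np.deg2rad(a)
        mean[in_tube] = (
            tissue.s0
            * np.sin(ar)
            * (1 - e1)
            / (1 - e1 * np.cos(ar))
            * np.exp(-te / tissue.t2star)
        )
    return mean


def simulate_scan(
    truth: VolumeSet,
    protocol: AcquisitionProtocol,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> VolumeSet:
    """Forward-simulate one SPGR/UTE scan: one magnitude volume per echo.

    Returns a VolumeSet with keys ``echo0``, ``echo1``, ... ordered as
    ``protocol.tes``.  ``noise_sigma=0`` returns the noiseless model exactly;
    otherwise Rician noise with the given seed (same seed, same volumes).
    """
    rng = np.random.default_rng(seed)
    sp = truth.grid.spacing
    out = {}
    for i, te in enumerate(protocol.tes):
        mean = _noiseless_echo(truth, protocol, te)
        out[f"echo{i}"] = VoxelVolume(_rician(mean, noise_sigma, rng), sp)
    return VolumeSet(out)


def simulate_ir_series(
    truth: VolumeSet,
    tis: Sequence[float],
    protocol: AcquisitionProtocol | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    inversion_efficiency: float = 1.0,
) -> list[VoxelVolume]:
    """Inversion-recovery series: per TI, magnitude |A - B exp(-TI/T1)|.

    Ideal inversion gives B = 2A with A = S0; ``inversion_efficiency`` e
    scales the inverted component, B = (1 + e) A.  The UTE readout protocol
    is accepted for bookkeeping; its short TE and low angle are absorbed into
    A in this reduced three-parameter form.  Rician noise as in
    :func:`simulate_scan`.
    """
    tis = np.asarray(tis, dtype=float)
    if np.any(np.diff(tis) <= 0):
        raise ValueError("inversion times must be strictly ascending")
    if not 0.0 <= inversion_efficiency <= 1.0:
        raise ValueError("inversion_efficiency must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t1 = truth["t1"].data
    s0 = truth["s0"].data
    in_tube = truth["t1"].valid
    sp = truth.grid.spacing
    out = []
    for ti in tis:
        mean = np.zeros(truth.grid.shape)
        rec = 1.0 - (1.0 + inversion_efficiency) * np.exp(-ti / t1[in_tube])
        mean[in_tube] = np.abs(s0[in_tube] * rec)
        out.append(VoxelVolume(_rician(mean, noise_sigma, rng), sp))
    return out


def noise_sigma_for_snr(
    snr: float, s0: float = DEFAULT_S0, fa: float = 11.0
) -> float:
    """Channel sigma for a target SNR: sigma = s0 * sin(fa) / SNR.

    SNR is quoted against the fully relaxed (TR >> T1) signal at TE = 0 for
    the mapping scan's flip angle — an object/transmit property independent
    of any tube's T1 — and one sigma serves all scans of a session.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    return float(s0 * np.sin(np.deg2rad(fa)) / snr)
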