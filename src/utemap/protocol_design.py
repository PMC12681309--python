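"""Protocol-design simulations: echo-time windows and flip-angle tradeoffs.

Two design questions precede a dual-scan relaxometry protocol:

* Which later echo TE3 gives a dual-echo T2* estimate useful sensitivity?
  From S3/S2 = exp(-(TE3-TE2)/T2*), requiring the signal to have decayed by
  at least ``decay_min`` (discrimination of long T2*) while retaining at
  least ``decay_floor`` of S2 (staying above the noise floor) bounds the
  usable T2* range in closed form.

* Which low flip angle FA1 for the T1-ratio scan?  FA1 must be small enough
  that S1 keeps little T1 weighting over the T1 range of interest, yet large
  enough that S1's residual T1 dependence — and S1 itself — stay clear of the
  noise.  Candidates are assessed, not auto-selected: the caller sees the
  curves and flags and makes the protocol choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_models import AcquisitionProtocol, TissueParams, signal_ratio, spgr_signal

__all__ = [
    "SensitivityWindow",
    "Fa1Assessment",
    "te3_sensitivity_window",
    "fa1_tradeoff",
]


@dataclass(frozen=True)
class SensitivityWindow:
    """Usable T2* range [t2star_low, t2star_high] for a dual-echo pair.

    ``decay_floor`` is the minimum retained fraction S3/S2 (noise guard);
    ``decay_min`` is the minimum decayed fraction 1 - S3/S2 (sensitivity
    guard).
    """

    te2: float
    te3: float
    t2star_low: float
    t2star_high: float
    decay_floor: float = 0.05
    decay_min: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.decay_floor < 1 - self.decay_min < 1:
            raise ValueError(
                f"need 0 < decay_floor < 1 - decay_min < 1, got "
                f"floor={self.decay_floor}, min={self.decay_min}"
            )
        if not self.t2star_low < self.t2star_high:
            raise ValueError("t2star_low must be below t2star_high")


def te3_sensitivity_window(
    te2: float,
    te3: float,
    decay_floor: float = 0.05,
    decay_min: float = 0.25,
) -> SensitivityWindow:
    """Closed-form T2* sensitivity window of a dual-echo pair.

    From S3/S2 = exp(-dTE/T2*) with dTE = te3 - te2:

        t2star_low  = dTE / ln(1/decay_floor)      (below this, S3 is noise)
        t2star_high = dTE / ln(1/(1 - decay_min))  (above this, too little decay)

    Both bounds scale linearly with the echo spacing.
    """
    if not te3 > te2:
        raise ValueError("te3 must exceed te2")
    if not 0 < decay_floor < 1 - decay_min < 1:
        raise ValueError(
            f"need 0 < decay_floor < 1 - decay_min < 1, got "
            f"floor={decay_floor}, min={decay_min}"
        )
    dte = te3 - te2
    return SensitivityWindow(
        te2=te2,
        te3=te3,
        t2star_low=dte / np.log(1.0 / decay_floor),
        t2star_high=dte / np.log(1.0 / (1.0 - decay_min)),
        decay_floor=decay_floor,
        decay_min=decay_min,
    )


@dataclass
class Fa1Assessment:
    """One FA1 candidate: signal/ratio curves over the T1 grid plus flags.

    ``weighting_below_noise``: S1's total T1 modulation over the grid is
    smaller than the noise level — the ratio carries no usable T1 contrast.
    ``ratio_degenerate``: S1 comes within the noise of S2 somewhere on the
    grid — the ratio saturates toward 1 and loses invertibility there.
    Admissible candidates fail both.
    """

    fa1: float
    t1_grid: np.ndarray
    s1_curve: np.ndarray
    s2_curve: np.ndarray
    ratio_curve: np.ndarray
    weighting_below_noise: bool
    ratio_degenerate: bool

    @property
    def admissible(self) -> bool:
        return not (self.weighting_below_noise or self.ratio_degenerate)


def fa1_tradeoff(
    p1_template: AcquisitionProtocol,
    p2: AcquisitionProtocol,
    fa1_candidates: list[float],
    t1_grid: np.ndarray | None = None,
    noise_level: float = 0.02,
) -> list[Fa1Assessment]:
    """Assess candidate low flip angles for the T1-ratio scan.

    ``noise_level`` is the assumed noise expressed as a fraction of the S2
    signal.  Signals are evaluated at TE = 0 with unit proton density (T2*
    and S0 scale both scans identically and cancel from every comparison).

    The default assessment grid spans 1-2500 ms: the T1 domain the dual-scan
    protocol is expected to quantify.  This is deliberately narrower than the
    4000 ms lookup grid — S1 and S2 cross near 2700-3400 ms for mid-range
    candidates, a degeneracy that matters only if those very long T1 values
    are themselves quantification targets.
    """
    grid = np.arange(1.0, 2501.0) if t1_grid is None else np.asarray(t1_grid, float)
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    for fa1 in fa1_candidates:
        # fa1 == fa2 is allowed through to be flagged as degenerate below
        if not 0 < fa1 <= p2.fa:
            raise ValueError(
                f"candidate FA1={fa1} must lie in (0, FA2={p2.fa}] degrees"
            )
    tissue = TissueParams(t1=grid, t2star=1.0, s0=1.0)
    s2 = np.asarray(spgr_signal(tissue, p2.tr, p2.fa, te=0.0))
    out = []
    for fa1 in fa1_candidates:
        p1 = AcquisitionProtocol(p1_template.tr, fa1, p1_template.tes, p1_template.label)
        s1 = np.asarray(spgr_signal(tissue, p1.tr, fa1, te=0.0))
        ratio = signal_ratio(grid, p1, p2) if p1.tes[0] == p2.tes[0] else s1 / s2
        weighting_flat = (s1.max() - s1.min()) < noise_level * s2.mean()
        degenerate = bool(np.any(np.abs(s1 - s2) < noise_level * s2))
        out.append(
            Fa1Assessment(
                fa1=float(fa1),
                t1_grid=grid,
                s1_curve=s1,
                s2_curve=s2,
                ratio_curve=np.asarray(ratio),
                weighting_below_noise=bool(weighting_flat),
                ratio_degenerate=degenerate,
            )
        )
    return out
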