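"""Closed-form spoiled gradient echo (SPGR) steady-state signal physics.

The SPGR magnitude signal at echo time TE is

    S = S0 * sin(a) * (1 - E1) / (1 - E1 * cos(a)) * exp(-TE / T2*),

with E1 = exp(-TR / T1) and a the flip angle.  Everything in this package —
the dual-echo T2* estimator, the lookup-table T1 estimator, the protocol
designer and the digital phantom simulator — is built on this expression.

Units follow the acquisition convention: times in ms, angles in degrees
(converted to radians internally), signals in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "AcquisitionProtocol",
    "TissueParams",
    "spgr_signal",
    "spgr_saturation",
    "inphase_echo_times",
    "ernst_angle",
    "signal_ratio",
    "load_protocols",
    "save_protocols",
    "default_protocols",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One SPGR/UTE scan: repetition time, nominal flip angle, echo times.

    Attributes
    ----------
    tr:
        Repetition time in ms, > 0.
    fa:
        Nominal flip angle in degrees, in (0, 180).
    tes:
        Echo times in ms, >= 0, strictly ascending, first echo < TR.
    label:
        Free-text description.
    """

    tr: float
    fa: float
    tes: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "tes", tuple(float(t) for t in self.tes))
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if not 0 < self.fa < 180:
            raise ValueError(f"flip angle must lie in (0, 180) deg, got {self.fa}")
        if len(self.tes) < 1:
            raise ValueError("at least one echo time is required")
        if any(t < 0 for t in self.tes):
            raise ValueError(f"echo times must be >= 0, got {self.tes}")
        if any(b <= a for a, b in zip(self.tes, self.tes[1:])):
            raise ValueError(f"echo times must be strictly ascending, got {self.tes}")
        if self.tes[0] >= self.tr:
            raise ValueError(
                f"first echo ({self.tes[0]} ms) must precede TR ({self.tr} ms)"
            )


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of one tissue/voxel; fields may be arrays."""

    t1: float | np.ndarray
    t2star: float | np.ndarray
    s0: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.t1) <= 0):
            raise ValueError("T1 must be positive")
        if np.any(np.asarray(self.t2star) <= 0):
            raise ValueError("T2* must be positive")
        if np.any(np.asarray(self.s0) < 0):
            raise ValueError("S0 must be nonnegative")


def spgr_saturation(
    t1: float | np.ndarray, tr: float | np.ndarray, fa: float | np.ndarray
) -> float | np.ndarray:
    """T1-saturation factor sin(a)(1-E1)/(1-E1 cos(a)), i.e. S/S0 at TE=0."""
    a = np.deg2rad(fa)
    e1 = np.exp(-np.asarray(tr, dtype=float) / np.asarray(t1, dtype=float))
    return np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def spgr_signal(
    tissue: TissueParams,
    tr: float,
    fa: float,
    te: float | np.ndarray,
) -> float | np.ndarray:
    """Steady-state SPGR signal for ideal spoiling; nonnegative, <= S0."""
    return (
        tissue.s0
        * spgr_saturation(tissue.t1, tr, fa)
        * np.exp(-np.asarray(te, dtype=float) / tissue.t2star)
    )


def inphase_echo_times(f0: float, shift: float = 3.3, n: int = 2) -> list[float]:
    """Echo times (ms) at which water and fat are in phase.

    The fat-water beat period is 1/(f0 * shift) with ``f0`` the scanner
    frequency in MHz and ``shift`` the chemical shift in ppm; in-phase echoes
    are its integer multiples.  Values are rounded to 0.01 ms, the precision
    at which protocols are reported.
    """
    if f0 <= 0 or shift <= 0:
        raise ValueError("f0 and shift must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    period_ms = 1000.0 / (f0 * shift)
    return [round(k * period_ms, 2) for k in range(1, n + 1)]


def ernst_angle(tr: float, t1: float) -> float:
    """Flip angle (degrees) maximizing the SPGR signal: arccos(exp(-TR/T1))."""
    if tr <= 0 or t1 <= 0:
        raise ValueError("TR and T1 must be positive")
    return float(np.rad2deg(np.arccos(np.exp(-tr / t1))))


def signal_ratio(
    t1: float | np.ndarray,
    p1: AcquisitionProtocol,
    p2: AcquisitionProtocol,
    b1_scale: float = 1.0,
) -> float | np.ndarray:
    """Predicted S1/S2 ratio between two differently T1-weighted scans.

    Evaluates

        S1/S2 = sin(a1)(1-E1^(1))(1-E1^(2) cos(a2))
                / [sin(a2)(1-E1^(2))(1-E1^(1) cos(a1))]

    with effective angles ``b1_scale * fa``; both scans share one transmit
    chain, so a single relative B1+ scale multiplies both nominal angles.
    S0 and the T2* decay cancel because the two compared echoes are acquired
    at identical TE — enforced here, since the cancellation is what makes the
    ratio a pure function of T1.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    fa_max = max(p1.fa, p2.fa)
    if not 0 < b1_scale < 180.0 / fa_max:
        raise ValueError(
            f"b1_scale {b1_scale} puts an effective angle outside (0, 180) deg"
        )
    if p1.tes[0] != p2.tes[0]:
        raise ValueError(
            "compared echoes must share one TE for T2* to cancel "
            f"(got {p1.tes[0]} vs {p2.tes[0]} ms)"
        )
    a1 = np.deg2rad(b1_scale * p1.fa)
    a2 = np.deg2rad(b1_scale * p2.fa)
    e1 = np.exp(-p1.tr / t1)
    e2 = np.exp(-p2.tr / t1)
    out = (np.sin(a1) * (1 - e1) * (1 - e2 * np.cos(a2))) / (
        np.sin(a2) * (1 - e2) * (1 - e1 * np.cos(a1))
    )
    return float(out) if out.ndim == 0 else out


# -- protocol configuration files ----------------------------------------


def load_protocols(path: str | Path) -> dict[str, AcquisitionProtocol]:
    """Load named acquisition protocols from a YAML config (one block per scan)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, block in raw.items():
        out[name] = AcquisitionProtocol(
            tr=float(block["tr"]),
            fa=float(block["fa"]),
            tes=tuple(float(t) for t in block["tes"]),
            label=str(block.get("label", name)),
        )
    return out


def save_protocols(protocols: dict[str, AcquisitionProtocol], path: str | Path) -> None:
    raw = {
        name: {"tr": p.tr, "fa": p.fa, "tes": list(p.tes), "label": p.label}
        for name, p in protocols.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def default_protocols() -> dict[str, AcquisitionProtocol]:
    """The shipped two-measurement UTE protocol.

    Measurement 1: single ultrashort echo at low flip angle (minimal T1
    weighting).  Measurement 2: dual/triple-echo scan at the Ernst angle for
    T1 ~ 500 ms, whose echoes drive T2* mapping and whose first echo pairs
    with measurement 1 for the T1 ratio.
    """
    from importlib.resources import files

    return load_protocols(str(files("utemap.data").joinpath("protocols.yaml")))


def protocol_pair(
    protocols: dict[str, AcquisitionProtocol] | None = None,
) -> tuple[AcquisitionProtocol, AcquisitionProtocol]:
    """(low-weighting S1 scan, T1/T2*-mapping S2 scan) from a config dict."""
    protocols = protocols or default_protocols()
    return protocols["measurement1"], protocols["measurement2"]
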