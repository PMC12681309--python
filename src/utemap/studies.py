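"""End-to-end phantom validation studies.

These functions run the full chain — phantom rendering, scan simulation,
mapping, VOI extraction, reference estimation — and return tidy tables,
one row per (replicate, VOI).  They are the programmatic equivalent of a
phantom validation session: simulate the tubes, map them with the fast
methods, and compare against the reference estimators (ETsME for T2*,
inversion recovery for T1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import (
    PhantomSpec,
    default_t1_phantom,
    default_t2star_phantom,
    render_truth,
    simulate_ir_series,
    simulate_scan,
)
from .signal_models import AcquisitionProtocol, protocol_pair
from .t1 import InversionSeries, build_lut_bank, ir_fit, map_t1
from .t2star import (
    EchoSeries,
    dual_echo_t2star,
    etsme_echo_times,
    etsme_reference,
    multi_echo_t2star,
)
from .validation import VOI, split_voi_slabs, tube_vois, voi_stats
from .volumes import VolumeSet, VoxelVolume

__all__ = [
    "etsme_protocol",
    "default_inversion_times",
    "ir_protocol",
    "run_t2star_phantom",
    "run_t1_phantom",
]

DEFAULT_TIS = np.geomspace(30.0, 8000.0, 22)
"""22 inversion times from 30 to 8000 ms (log-spaced to weight the early
recovery, where short-T1 curvature lives)."""


def etsme_protocol() -> AcquisitionProtocol:
    """The pooled echo-train-shifted reference acquisition (26 unique TEs)."""
    return AcquisitionProtocol(
        tr=13.0,
        fa=12.0,
        tes=tuple(etsme_echo_times()),
        label="ETsME reference: 22 shifted first echoes + 4 fixed echoes",
    )


def default_inversion_times() -> np.ndarray:
    return DEFAULT_TIS.copy()


def ir_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol(
        tr=4.4, fa=6.0, tes=(0.03,), label="IR-UTE readout (reference T1)"
    )


def _study_vois(
    truth: VolumeSet, margin_voxels: int, vois_per_tube: int
) -> list[tuple[int, VOI]]:
    out = []
    for voi in tube_vois(truth, margin_voxels=margin_voxels):
        tube_id = int(voi.label.removeprefix("tube"))
        if vois_per_tube > 1:
            for sub in split_voi_slabs(voi, vois_per_tube):
                out.append((tube_id, sub))
        else:
            out.append((tube_id, voi))
    return out


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _voi_signal_series(
    scan: VolumeSet, tes: np.ndarray, voi: VOI
) -> EchoSeries:
    means = np.array(
        [float(scan[f"echo{i}"].data[voi.mask].mean()) for i in range(tes.size)]
    )
    return EchoSeries(tes, means)


def run_t2star_phantom(
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
    spec: PhantomSpec | None = None,
    margin_voxels: int = 3,
    vois_per_tube: int = 2,
    t2_cap: float = 100.0,
) -> pd.DataFrame:
    """Simulate the T2* phantom and map it with all three fast methods.

    Per replicate: one mapping scan (echoes 0.03/2.46/4.92 ms) and one ETsME
    reference acquisition, both at ``noise_sigma``.  Columns: replicate, voi,
    tube, ``t2star_true``, ``ref_etsme`` and per-method VOI means ``t2_3te``,
    ``t2_2te246``, ``t2_2te492``.
    """
    spec = spec or default_t2star_phantom()
    truth = render_truth(spec)
    _, p2 = protocol_pair()
    etsme = etsme_protocol()
    etsme_tes = np.asarray(etsme.tes)
    vois = _study_vois(truth, margin_voxels, vois_per_tube)
    tube_truth = {i + 1: t.t2star for i, t in enumerate(spec.tubes)}
    seeds = _child_seeds(seed, 2 * n_replicates)
    rows = []
    for rep in range(n_replicates):
        scan = simulate_scan(truth, p2, noise_sigma, seed=int(seeds[2 * rep]))
        ref_scan = simulate_scan(truth, etsme, noise_sigma, seed=int(seeds[2 * rep + 1]))
        e0, e1, e2 = (scan[f"echo{i}"] for i in range(3))
        m246 = dual_echo_t2star(e0, e1, p2.tes[0], p2.tes[1], t2_cap=t2_cap).volume
        m492 = dual_echo_t2star(e0, e2, p2.tes[0], p2.tes[2], t2_cap=t2_cap).volume
        m3te = multi_echo_t2star([e0, e1, e2], p2.tes, t2_cap=t2_cap).volume
        for tube_id, voi in vois:
            ref = etsme_reference(_voi_signal_series(ref_scan, etsme_tes, voi))
            rows.append(
                {
                    "replicate": rep,
                    "voi": voi.label,
                    "tube": tube_id,
                    "t2star_true": tube_truth[tube_id],
                    "ref_etsme": ref,
                    "t2_3te": voi_stats(m3te, voi).mean,
                    "t2_2te246": voi_stats(m246, voi).mean,
                    "t2_2te492": voi_stats(m492, voi).mean,
                }
            )
    return pd.DataFrame(rows)


def run_t1_phantom(
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
    spec: PhantomSpec | None = None,
    margin_voxels: int = 3,
    vois_per_tube: int = 2,
    tis: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate the T1 phantom; LUT-map it and fit the IR reference.

    Per replicate: the low-weighting scan (S1), the mapping scan (S2), and a
    22-TI inversion-recovery series, all at ``noise_sigma``.  The LUT bank is
    selected per voxel through the phantom's ground-truth B1+ field.
    Columns: replicate, voi, tube, ``t1_true``, ``ref_ir``, ``t1_lut``.
    """
    spec = spec or default_t1_phantom()
    truth = render_truth(spec)
    p1, p2 = protocol_pair()
    tis = DEFAULT_TIS if tis is None else np.asarray(tis, dtype=float)
    b1 = truth["b1"]
    eff = np.rint(b1.data * p2.fa).astype(int)
    bank = build_lut_bank(p1, p2, fa_lo=max(1, eff.min()), fa_hi=min(179, eff.max()))
    vois = _study_vois(truth, margin_voxels, vois_per_tube)
    tube_truth = {i + 1: t.t1 for i, t in enumerate(spec.tubes)}
    seeds = _child_seeds(seed, 3 * n_replicates)
    rows = []
    for rep in range(n_replicates):
        s1 = simulate_scan(truth, p1, noise_sigma, seed=int(seeds[3 * rep]))["echo0"]
        s2 = simulate_scan(truth, p2, noise_sigma, seed=int(seeds[3 * rep + 1]))["echo0"]
        ir_vols = simulate_ir_series(
            truth, tis, ir_protocol(), noise_sigma, seed=int(seeds[3 * rep + 2])
        )
        t1_map = map_t1(s1, s2, b1, bank).volume
        for tube_id, voi in vois:
            means = np.array([float(v.data[voi.mask].mean()) for v in ir_vols])
            ref = ir_fit(InversionSeries(tis, means)).t1
            rows.append(
                {
                    "replicate": rep,
                    "voi": voi.label,
                    "tube": tube_id,
                    "t1_true": tube_truth[tube_id],
                    "ref_ir": ref,
                    "t1_lut": voi_stats(t1_map, voi).mean,
                }
            )
    return pd.DataFrame(rows)
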