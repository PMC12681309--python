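"""Lookup-table T1 mapping on the ten-tube phantom, vs inversion recovery.

Builds the S1/S2 ratio lookup table, shows how transmit-field (B1+) scale
shifts the curve, then runs the simulated study at SNR 50: voxelwise LUT
inversion with B1+ correction against the 22-TI inversion-recovery
reference.
"""

import numpy as np

import utemap as u

p1, p2 = u.protocol_pair()
lut = u.build_lut(p1, p2)
print(f"lookup table: {len(lut)} entries, T1 {lut.t1_grid[0]:g}-{lut.t1_grid[-1]:g} ms")
for t1 in (1, 300, 800, 1300, 4000):
    print(f"  T1 {t1:5d} ms -> predicted S1/S2 = {lut.ratios[t1 - 1]:.4f}")
for b1 in (0.8, 1.2):
    shifted = u.build_lut(p1, p2, b1_scale=b1)
    t1_hat = u.lut_invert(float(lut.ratios[799]), shifted).t1
    print(
        f"inverting the nominal-angle ratio of an 800 ms sample through a "
        f"B1+={b1:g} table gives {t1_hat:.0f} ms -> why per-voxel B1+ correction exists"
    )

sigma = u.noise_sigma_for_snr(50.0)
df = u.run_t1_phantom(noise_sigma=sigma, seed=11)
print("\nper-tube T1 (ms) at SNR 50, 2 VOIs per tube:")
print(
    df.groupby("tube")[["t1_true", "ref_ir", "t1_lut"]].mean().round(1).to_string()
)
rep = u.bland_altman(list(zip(df.ref_ir, df.t1_lut)), percent=True)
print(
    f"\nLUT vs IR reference: mean difference {rep.mean_difference:+.1f}% "
    f"+/- {rep.sd_difference:.1f}% (LoA {rep.loa_low:+.1f}% .. {rep.loa_high:+.1f}%)"
)
print("The negative mean difference is a slight LUT overestimate: the Rician "
      "floor inflates the weak S1 signal, nudging the ratio (and T1) upward.")
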