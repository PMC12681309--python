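"""Simulate the seven-tube T2* phantom and map it three ways.

Runs the full chain at SNR 50 — forward simulation with Rician noise,
dual-echo mapping with both later-echo choices, the three-echo fit, and the
echo-train-shifted reference — and prints per-tube means.  The table shows
the central echo-time tradeoff: the 4.92 ms later echo overestimates short
T2* (its signal sits on the noise floor), the 2.46 ms echo degrades for
long T2* (too little decay between echoes).
"""

import utemap as u

sigma = u.noise_sigma_for_snr(50.0)
df = u.run_t2star_phantom(noise_sigma=sigma, seed=7, n_replicates=10)
per_tube = df.groupby("tube")[
    ["t2star_true", "ref_etsme", "t2_3te", "t2_2te246", "t2_2te492"]
].mean()
print("per-tube mean T2* (ms) over 10 noisy replicates, 2 VOIs per tube:")
print(per_tube.round(2).to_string())

print("\nagreement with the ETsME reference (differences = reference - method):")
for col in ("t2_3te", "t2_2te246", "t2_2te492"):
    rep = u.bland_altman(list(zip(df.ref_etsme, df[col])), percent=True)
    print(
        f"  {col:10s}: mean {rep.mean_difference:+6.1f}%  "
        f"LoA [{rep.loa_low:+6.1f}%, {rep.loa_high:+6.1f}%]  (n={rep.n})"
    )
print(
    "\nNegative mean differences are method overestimates; the 2.46 ms "
    "variant tracks the reference best for tubes at or below ~11 ms."
)
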