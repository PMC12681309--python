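# utemap

Fast combined T1/T2\* relaxometry for ultrashort echo time (UTE) MRI.

Musculoskeletal tissues with fast transverse relaxation — tendons,
ligaments, menisci, cortical bone — decay within a few milliseconds and are
invisible to conventional echo times. UTE acquisitions capture them, but
quantitative T1 and T2\* mapping then usually costs tens of minutes of scan
time. `utemap` implements a two-scan strategy that quantifies both
parameters from a handful of spoiled-gradient-echo (SPGR) UTE volumes,
together with everything needed to validate it end to end on synthetic
data: reference estimators, a digital multi-tube phantom simulator,
agreement statistics, and protocol-design calculators.

## The model

All estimators derive from the SPGR steady-state signal

```
S = S0 · sin α · (1 − E1) / (1 − E1 cos α) · exp(−TE/T2*),   E1 = exp(−TR/T1)
```

**T2\*** comes from two echoes of one scan (TE2 ultrashort, TE3 at a
fat–water in-phase time):

```
T2* = (TE3 − TE2) / ln(S2/S3)
```

**T1** comes from the ratio of two scans with different T1 weighting
(low-angle S1 vs Ernst-angle S2, both at the same ultrashort TE so S0 and
T2\* cancel). The ratio is a strictly monotone function of T1, tabulated
over a 1–4000 ms grid (1 ms steps) and inverted per voxel. Transmit-field
inhomogeneity is handled by a bank of lookup tables indexed by the local
effective flip angle from a relative B1+ map.

Reference estimators for validation: an echo-train-shifted multi-echo
(ETsME) mono-exponential fit for T2\*, and three-parameter magnitude
inversion-recovery fitting `|A − B·exp(−TI/T1)|` for T1. Agreement is
summarized Bland–Altman style (mean difference ± 1.96 SD, reference −
method, as percent of reference).

## A worked example

```python
import utemap as u

sigma = u.noise_sigma_for_snr(50.0)            # Rician channel noise, SNR 50
df = u.run_t2star_phantom(noise_sigma=sigma, seed=7, n_replicates=10)
print(df.groupby("tube")[["t2star_true", "ref_etsme",
                          "t2_2te246", "t2_2te492"]].mean().round(2))
```

```
      t2star_true  ref_etsme  t2_2te246  t2_2te492
tube
1             1.0       1.01       1.11       1.88
2             2.0       2.05       2.05       2.21
3             3.0       3.10       3.11       3.10
4             5.0       5.09       5.30       5.17
5             8.0       8.07       9.32       8.39
6            12.0      12.11      16.34      13.10
7            20.0      20.13      27.81      24.84
```

Each row is one tube of the simulated seven-tube T2\* phantom (mean over
eroded cylindrical VOIs, 10 noisy replicates). The table shows the central
echo-time tradeoff: with the later echo at 4.92 ms the 1–2 ms tubes are
overestimated (the decayed echo sits on the Rician noise floor), while the
2.46 ms echo stays accurate there but degrades beyond ~10 ms where too
little decay accumulates between echoes. The ETsME reference column tracks
the truth across the whole range.

The `examples/` directory holds one short script per capability: protocol
design (`01`), T2\* phantom mapping (`02`), lookup-table T1 mapping with
B1+ correction (`03`), and the preprocessing chain (`04`). A thin CLI
(`utemap simulate | map-t2star | map-t1 | build-lut | preprocess |
subtract | validate | design-protocol`) wraps the same functions for
NIfTI volumes on disk.

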