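# Methods

This note documents the models, estimators, simulator conventions and
numerical choices behind `utemap`, and what the synthetic validation does
and does not demonstrate.

## Signal model and protocol

Every estimator is built on the ideally spoiled gradient-echo steady state,

S = S0 · sin α · (1 − E1)/(1 − E1 cos α) · e^(−TE/T2\*),  E1 = e^(−TR/T1),

with times in ms, angles in degrees, signals in arbitrary units. The
closed form is verified in the tests against an independent brute-force
oracle that iterates excitation + longitudinal relaxation with perfect
spoiling to its fixed point (run to convergence at tolerance 1e−14; a fixed
small iteration count would not reach 1e−6 relative agreement for
TR ≪ T1).

The shipped default protocol (`utemap/data/protocols.yaml`) is a
two-measurement scheme at 3 T (123.256 MHz):

* measurement 1 — TR 4.92 ms, FA 3°, TE 0.03 ms: minimal T1 weighting;
* measurement 2 — TR 9.24 ms, FA 11°, TE 0.03/2.46/4.92 ms: the mapping
  scan, at the Ernst angle for T1 ≈ 500 ms (arccos e^(−TR/T1) = 10.98° →
  11°), with later echoes at fat–water in-phase times
  (k · 1000/(f0·shift) ms, rounded to 0.01 ms — the precision at which
  protocols are reported).

## T2\* estimation

* **Dual-echo**: T2\* = (TE3 − TE2)/ln(S2/S3) per voxel. Voxels with
  S3 ≤ 0 or S2 ≤ S3 are invalid (non-decaying signal has no finite
  positive T2\*). Estimates above a cap (default 100 ms) are clipped to
  the cap and flagged rather than discarded, so region statistics can
  choose; defaults include them, which is what makes the long-T2\*
  overestimation of noisy short-spacing protocols visible in the
  statistics instead of silently censored.
* **Multi-echo (3TE)**: log-linear least squares of ln S against TE with
  weights ∝ S², the standard variance-stabilizing weighting for
  log-transformed exponentials. Deterministic and failure-free for the
  3-point mapping case. Non-positive samples are excluded, never clamped
  to ε — clamping would fabricate arbitrarily long decay constants.
* **ETsME reference**: the echo-train-shifted acquisition pools 22 sliding
  first echoes (0.03–1.5 ms) with 4 fixed later echoes
  (4.92/7.38/9.84/12.3 ms; TR 13 ms, FA 12°) into one 26-point decay
  curve, fitted per VOI on the VOI-mean signal. The reference fit defaults
  to a nonlinear least-squares polish (started from the log-linear
  solution): for tubes with T2\* of 1–2 ms the fixed echoes lie entirely
  on the Rician noise floor, and in log space those floor samples acquire
  enormous leverage (the log stretches small magnitudes), inflating a
  log-linear reference by tens of percent; on the signal scale the same
  samples are nearly weightless. A `shifted_only` flag restricts the fit
  to the sliding echoes instead; the default uses all samples.

Noiseless, all three estimators invert the forward model exactly (the
dual-echo formula is the two-point log-linear fit), so method differences
arise only under noise — which is the point of the echo-time choice: the
usable T2\* window of a dual-echo pair is
[ΔTE/ln(1/f), ΔTE/ln(1/(1−d))] for retained fraction f (default 0.05) and
minimum decay d (default 0.25), i.e. about 0.81–8.45 ms for TE3 = 2.46 ms
and twice that for 4.92 ms.

## T1 estimation

The ratio of the two measurements' equal-TE echoes cancels S0 and T2\* and
is strictly monotone in T1 for the default protocol pair; monotonicity is
asserted when a table is built and non-monotone protocol pairs refuse to
build. Tables span 1–4000 ms in 1 ms steps; inversion picks the grid entry
with the nearest predicted ratio (ties toward the smaller T1), reproducing
discrete-lookup behavior; linear interpolation is available as a toggle.
Ratios beyond the table clamp to the boundary T1 and are flagged, keeping
maps visually complete.

B1+ handling: both scans share one transmit chain, so a single relative
scale multiplies both nominal angles. The bank is keyed by
round(b1 · FA2) over 1–179° (sin 180° = 0 leaves no signal, so no ratio
exists at exactly 180°), and FA1 is scaled by the same continuous factor
rather than independently rounded — rounding the two angles independently
would break their physical coupling. Noiseless with matched B1+, the
map error is bounded by grid quantization (≤ 1 ms); ignoring a ±20%
transmit error instead shifts a 500 ms sample by hundreds of ms, which is
why the correction exists.

The reference is three-parameter magnitude inversion recovery,
|A − B e^(−TI/T1)|, fitted by trust-region least squares multi-started
over 16 log-spaced T1 values (10–8000 ms), keeping the lowest residual.
The magnitude (unsigned) model matches magnitude images; no polarity
restoration is attempted. Fits are flagged degenerate when B ≈ 0, T1
pins at the search bounds, or T1 falls below the first TI (the inversion
would have decayed before any sample).

## Preprocessing

* B1+ maps are resampled onto the imaging grid by trilinear interpolation
  with field-of-view centers aligned (nearest-inside values at edges,
  nearest-neighbor along degenerate single-slice axes), then smoothed by a
  trivariate polynomial fit over valid voxels — transmit fields are
  spatially smooth, so the fit removes measurement noise that would
  otherwise propagate into flip-angle correction. Degree 3 by default, on
  coordinates normalized to [−1,1]³ for conditioning; the degree
  auto-reduces (with a warning) when the valid voxels cannot support it.
  Fit-then-evaluate is a projection: applying it to its own output is a
  no-op.
* Denoising is patchwise nonlocal means (via scikit-image) with the
  channel noise level estimated from the Rayleigh-distributed background
  (sd/√((4−π)/2)) when a background mask exists, wavelet-estimated
  otherwise; `strength` scales the filtering parameter and 0 is the exact
  identity. It is optional and off by default in the validation studies so
  estimator properties are assessed deterministically — the mapping math,
  not the filter, is under test.
* Background masking thresholds at a fraction (default 0.1) of the 99th
  percentile of valid signal — a robust maximum that resists hot pixels.
* Subtraction images S2 − S3 highlight fast-relaxing structures (at equal
  proton density, short-T2\* tissue loses more signal between echoes);
  negative values are retained.
* Co-registration is out of scope: simulated volumes share a grid by
  construction, and `check_alignment` (phase correlation) warns if that
  contract is broken by more than half a voxel.

## Digital phantoms and noise

Two default phantoms on a 64×64×16 grid at 0.8 mm isotropic spacing, tubes
as parallel cylinders on a ring, proton density 100 inside and 0 outside:

* T2\* phantom: 7 tubes at {1, 2, 3, 5, 8, 12, 20} ms, common T1 1000 ms —
  covering the 1–20 ms range with denser sampling at the short end where
  echo-time choices matter;
* T1 phantom: 10 tubes uniformly spanning 300–1300 ms, common T2\* 30 ms.

Per-tube values within these ranges are this package's choice; the study
design fixes only the ranges and tube counts. The B1+ field is a
polynomial (constant 1 by default; `with_b1_inhomogeneity` installs a
quadratic bowl falling to 1 − amplitude at the corners).

Noise is Rician: magnitude = √((mean+g₁)² + g₂²), g ~ N(0, σ²). This is
deliberate — the magnitude noise floor is what biases log-ratio T2\*
estimation when the later echo decays into it; Gaussian noise would hide
the effect the echo-time design controls. SNR convention:
σ = S0 · sin(FA₂)/SNR, quoting SNR against the fully relaxed TE = 0 signal
at the mapping scan's flip angle. This anchors σ to the object and
transmit settings rather than to any tube's T1, and one σ serves every
scan of a session, as befits a receive-chain property. At the default
SNR 50 the mapping scan's in-tube image SNR is ≈ 17 at the first echo.
Identical spec + seed reproduce identical volumes.

The inversion-recovery series uses the reduced three-parameter form with
A = S0 and B = (1 + e)·A (ideal inversion e = 1 by default; configurable),
at 22 log-spaced TIs from 30 to 8000 ms — log-spacing weights the early
recovery where short-T1 curvature lives.

What the simulator does **not** emulate: k-space trajectories and the
TE spread across a stack-of-spirals readout, chemical shift and fat–water
interference, imperfect spoiling, slice profiles, motion, receive-field
bias, or magic-angle orientation dependence. Passing the synthetic studies
therefore demonstrates the estimators' correctness and noise behavior
under the stated signal model, not robustness to those acquisition
non-idealities.

## Validation statistics

VOIs erode each tube in-plane by a margin (default 3 voxels) using a
per-slice Euclidean distance transform (threshold margin + 0.5, since
voxel centers sit half a voxel inside the wall) — this tracks the
continuum geometry (radius r − margin) more faithfully than
structuring-element erosion. Each tube contributes two axial slabs by
default, making the VOI the unit of agreement analysis. Statistics use
valid voxels only; CV = sd/mean with sd of n = 1 defined as 0.
Bland–Altman differences are reference − method, in percent of reference
by default (zero-reference pairs excluded with a warning), with limits of
agreement exactly mean ± 1.96 sd.

## Protocol design

The FA1 tradeoff assessment evaluates candidate low angles on a default
grid of 1–2500 ms — the T1 domain this protocol family is expected to
quantify, deliberately narrower than the 4000 ms lookup grid. Two flags:
T1-weighting below the noise (max−min of S1 across the grid smaller than
the noise level × mean S2) and ratio degeneracy (S1 within noise of S2
somewhere on the grid). S1 crosses S2 near 2700–3400 ms for mid-range
candidates, so extending the assessment grid far beyond the quantification
target flags nearly every usable angle; with the default grid, 1° fails
the weighting test at 2% noise and 3° is admissible with comfortable
margins — matching the narrative choice of 3° as the compromise between
weighting and signal. The noise level is operationalized as a fraction of
the S2 signal (default 0.02). Candidates are assessed and reported, never
auto-selected.

## Study sizes and runtime

The bundled studies run the full chain (render → simulate → map → VOI →
reference) on the 64×64×16 grid; the noise-floor bias study uses 200
replicates of the seven-tube phantom (≈ half a minute on one CPU), and
agreement studies use one replicate with two VOIs per tube unless asked
otherwise. All stochastic study entry points take explicit seeds and
spawn per-scan child seeds from them.

## Known limitations

* Mono-exponential decay only; collagen-bound vs free water compartments
  are not separated, so collagen-rich tissue will read as a weighted
  average (multi-exponential modeling is out of scope).
* The dual-echo estimator has no usable sensitivity below ~0.8 ms T2\*
  with the default echoes; sub-millisecond species (cortical bone) are
  outside the design window.
* LUT T1 accuracy degrades where the ratio curve flattens (very long T1)
  and under strong transmit error at the field-of-view edge; the bank
  corrects only what the B1+ map sees.
* The IR reference assumes inversion works; for very short T2\* species
  inversion pulses are ineffective in reality, a physics limitation the
  reduced three-parameter simulation does not model.
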