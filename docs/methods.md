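# Methods

## Signal model

The package models a segmented inversion-recovery sequence with two spoiled
gradient-echo (GRE) readout blocks per cycle — the MP2RAGE family, including
the multi-echo variant (MP2RAGEME) in which the second block acquires several
echoes.  One cycle of duration `TR_cycle` consists of: an adiabatic inversion
(`Mz → −η·Mz`, efficiency `η`), free relaxation over a gap `TA`, `n` low-angle
excitations at flip `α₁` spaced `TR₁` apart, a gap `TB`, `n` excitations at
`α₂` spaced `TR₂`, and a terminal recovery gap `TC`.  Inversion times `TI₁`
and `TI₂` are defined at the temporal center of their block (linear
phase-encode ordering), so

```
TA = TI₁ − (n/2)·TR₁
TB = (TI₂ − TI₁) − (n/2)·(TR₁ + TR₂)
TC = TR_cycle − TI₂ − (n/2)·TR₂
```

and `TA + n·TR₁ + TB + n·TR₂ + TC = TR_cycle` exactly (the inversion pulse is
modelled as instantaneous).

Under ideal spoiling every event maps the longitudinal magnetization
affinely, `Mz → A·Mz + B`: relaxation over `t` has `A = e^(−t/T1)`,
`B = M0(1 − e^(−t/T1))`; an excitation contributes `cos(b1·α)`; `k` identical
excitation–relaxation steps compose in closed form via `Aᵏ`.  The whole cycle
is affine and contractive, so the periodic steady state is the fixed point
`Mz* = B_cycle / (1 − A_cycle)` — computed directly, without settling
iterations, and broadcast over arrays of T1 and relative transmit field.
Tests verify this fixed point against (a) explicit cycle iteration to 1e−10
and (b) an independent sequential Bloch integrator (including a literal
millisecond-stepping variant) to 1e−6.

Echo signals are `sin(b1·α)·Mz·exp(−TE/T2*)` with `Mz` taken just before the
center excitation.  The two inversion images combine into the UNI (ratio)
image `S₁S₂/(S₁² + S₂²)`, bounded in [−0.5, 0.5] and invariant to joint
scaling of the inputs, hence free of M0, receive-field, and — because the
first echo of the second block matches TE₁ — T2* weighting.  For multi-echo
protocols the UNI always uses the first second-block echo.

Model assumptions (standard for this family): perfect spoiling, B1 scales
the excitation flip angles linearly and does not affect the adiabatic
inversion, no relaxation during pulses, single-compartment mono-exponential
relaxation.

## Protocols and parameters

Bundled protocol files (`mp2rageme.yaml`, `mp2rage.yaml`, `megre.yaml`)
encode the 7 T comparison protocols: MP2RAGEME with `TR_cycle` 6.72 s,
TR₁/TR₂ 6.2/31.4 ms, TE₁ 3 ms, TE₂ 3/11.5/20/28.5 ms, TI 670/3855 ms, flips
7°/6°, 150 lines × 147 readouts; MP2RAGE with TR 6 s, TI 1000/3200 ms; and a
12° multi-echo GRE at TR 31.4 ms.  `inv_efficiency` defaults to 0.96 in the
`ProtocolParams` type (a typical adiabatic value) but the bundled files set
1.0, which all simulation studies use.  Timing arithmetic is in milliseconds
internally; the cycle TR is in seconds at the interface.

The timing audit reports the scan duration (`n_readouts · TR_cycle`) and
*two* dead-time percentages — all three gaps `(TA+TB+TC)/TR_cycle` and the
tail-only `TC/TR_cycle` — because "dead time" admits both readings and
commonly quoted percentages for these protocols are not reproduced by either
definition (16.1%/7.6% for the multi-echo protocol, 69%/39% for the
single-echo one).  Neither number is asserted in tests.

## T1 quantification

A lookup table samples the forward model on a dense grid — T1 from 0.1 to
6.0 s at 1 ms, relative B1 from 0.6 to 1.4 at 0.01 (margin around the
physiological 0.8–1.2) — and records, per B1 column, the branch on which UNI
is strictly decreasing in T1.  Short-T1 and (at strongly reduced transmit)
long-T1 fold-over tails are excluded; intensities outside the branch clamp
to its ends and clear the validity mask, resolving ambiguity conservatively.

Volume decoding solves the bilinear table by vectorized bisection in T1 at
each voxel's B1 (45 iterations, resolution ≪ grid step); scalar column
inversion uses monotone piecewise-cubic (PCHIP) interpolation.  With the
1 ms grid the two interpolants differ by far less than the quantization, and
a noiseless encode–decode round trip is exact to ≤ 1–2 ms.  Low-resolution
B1 maps are median-smoothed (3³ kernel) and trilinearly upsampled; their
resampling scheme is a package choice, as acquisitions rarely document one.

## T2* quantification

Mono-exponential fits use signal-weighted log-linear least squares (weights
= squared signal), which is deterministic, exactly unbiased on noiseless
model-matched data, and at magnitude SNR 30 shows a median bias well under
5% for tissue-like T2*.  An optional noise-floor guard drops echoes below
3× a supplied noise SD (at least two retained); an optional
Levenberg–Marquardt refinement exists behind a flag.  Voxels with
non-positive fitted decay (constant or empty signal) are flagged invalid
rather than raised.

## Transmit-field sensitivity study

Contrast curves are simulated at relative B1 {0.8, 1.0, 1.2} exactly;
intensity ranges are max − min over that three-point set on the UNI scale
(ranges of 0.05–0.1 are meaningful only on this [−0.5, 0.5] scale).
Apparent T1 encodes at the actual field and decodes through the nominal
column.  Reference tissue T1s are WM 1.15 s, GM 1.85 s, CSF 4.0 s, matching
the blurring study for internal consistency.

Under this amplitude model the simulated white-matter intensity ranges are
0.110 (multi-echo) and 0.057 (single-echo) and the apparent-T1 spans are
1.04–1.29 s and 1.08–1.22 s.  Reference spans of 0.9–1.4 s and 1.0–1.3 s
reported for the same experiment correspond, in this model, to an effective amplitude
excursion of about 0.64–1.44 — i.e. to flip angles scaled by the *square* of
the relative field — which would in turn double the intensity ranges.  No
single field-scaling convention reproduces both published result sets; the
package keeps the physically standard linear amplitude scaling and reports
its honest outputs.  Likewise, the model makes the CSF intensity spread
slightly *wider* for the multi-echo protocol (0.18 vs 0.16), not narrower;
this ordering is not asserted.

## T1-induced blurring (point-spread-function) study

A 21×21-voxel square of GM in a 150×150 WM (or CSF) background is "acquired"
line by line: per-excitation steady-state signals for each compartment, one
image per excitation, Fourier transform along the phase-encode axis, k-space
line *i* of each block taken from excitation *i* (sequential ordering, DC at
the center excitation), inverse transform, complex UNI combination.  A
30×30 square is supported as a parameter.  Encoding is one-dimensional; the
readout axis is treated as fully sampled within an excitation.  The
simulation is noise-free and uses equal M0 for both compartments, since the
experiment isolates T1-driven signal evolution.

Blur is the maximum deviation of the phase-direction profile at the four
boundary-adjacent voxels, as a percentage of the tissue UNI contrast:
5.1% for GM-in-WM and 7.5% for GM-in-CSF under the multi-echo protocol
(1.8%/3.6% for the single-echo one).  The readout-direction profile keeps a
perfectly sharp edge; it carries a ripple below 1% of the contrast that is
Gibbs-type leakage from the *orthogonal* boundaries (the k-space modulation
is discontinuous where the sequential ordering wraps), not readout blur.  A
frozen-magnetization control (identical signal at every excitation)
reconstructs exactly, attributing all blur to signal evolution.

## Synthetic phantom

A nested-ellipsoid layout: CSF surround, GM shell, WM core, and six
spherical deep-gray nuclei (caudate, putamen, thalamus, red nucleus,
substantia nigra, subthalamic nucleus).  Tissue T1/T2* defaults are typical
7 T values for these structures (e.g. WM 1.19 s / 26.7 ms, GM 2.00 s /
32.4 ms); CSF T2* (200 ms) and the proton densities (WM 0.70, GM 0.82,
nuclei 0.80, CSF 1.0) are generic literature-style choices.  The relative
transmit field is a seeded random quadratic polynomial min–max scaled into
[0.8, 1.2].  Complex Gaussian noise gives Rician magnitudes; the noise SD is
the WM second-block first-echo signal divided by the configured SNR
(default 30).  The UNI image is formed from the noisy complex signals, as a
scanner would.  Phase volumes are a smooth synthetic field linear in TE,
written purely so outputs are format-complete for downstream susceptibility
tools; no susceptibility physics is modelled.

The default grid is 64³ at 0.64 mm.  This is a deliberately scaled-down
problem size; it keeps every nucleus ROI ≥ ~290 voxels so that ROI medians
at SNR 30 are statistically stable (at ~200 voxels the sampling error of a
median alone approaches the 2% recovery tolerance).  Everything is
deterministic given the seed, including the noise and the field.

What the phantom does *not* emulate: partial-volume mixing at boundaries,
receive-field bias, motion, flow, susceptibility-induced dephasing, spatial
noise correlation from parallel imaging, and chemical shift.  Passing
recovery tests therefore demonstrate the correctness of the forward/inverse
model chain under the stated noise model, not robustness to those in-vivo
effects.

## Agreement statistics

Bland–Altman quantities on paired values: mean difference, reproducibility
coefficient `1.96·SD(diff)`, coefficient of variation
`100·SD(diff)/mean(level)`, squared Pearson correlation of the pair, and a
Kolmogorov–Smirnov test of the mean/SD-standardized differences against the
standard normal (a Lilliefors-style caveat applies to its nominal p-value).

## Numerical choices and degenerate inputs

- Steady state: closed-form affine fixed point; the iterative path exists
  for cross-checking and converges to 1e−10 in ≲ 20 cycles for tissue T1s.
- Zero UNI denominator (both signals zero) returns 0 with a warning.
- Even/odd phantom centering floors the offset; `n_lines` odd uses
  `n // 2` as the center excitation.
- T2* fit ties: voxels where the weighted design is singular are invalid.
- Lookup grids must be strictly increasing; a non-monotone column (possible
  only for pathological protocols) raises an error naming the fold-over T1.
- The B1-sensitivity and blurring studies are deterministic; the only
  randomness in the package is the phantom noise and field, both seeded.

## Known limitations

- The inversion is ideal-adiabatic: transmit-field effects on inversion
  efficiency are not modelled (they are known to matter at strongly reduced
  B1).
- Quantification assumes the signed UNI is available; magnitude-only
  reconstruction (losing the sign of the first inversion) is not supported.
- The pipeline performs no registration, brain extraction, or segmentation;
  labels must be supplied (the phantom provides its own ground truth).
- Susceptibility mapping is out of scope; phase outputs are synthetic
  placeholders.
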