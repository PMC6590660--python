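# mp2rageme

Quantitative MRI toolkit for the MP2RAGEME sequence — the multi-echo
extension of MP2RAGE that measures T1, T2*, and (upstream of external QSM
tools) susceptibility-ready phase in a single 7 T acquisition.  The package
is aimed at physicists and methods researchers who want to simulate,
understand, or quantify this sequence family: it implements the Bloch signal
model of the segmented inversion-recovery dual-GRE cycle, lookup-table T1
mapping with transmit-field (B1+) correction, multi-echo T2* fitting, the
classic transmit-sensitivity and T1-blurring simulation experiments, and a
synthetic 3-D phantom for end-to-end validation.

## The model in brief

One cycle: adiabatic inversion → gap `TA` → `n` excitations at `α₁`/`TR₁`
(single echo) → gap `TB` → `n` excitations at `α₂`/`TR₂` (multi-echo) → gap
`TC`, repeating every `TR_MP2RAGE`.  With ideal spoiling each event acts
affinely on `Mz`, so the periodic steady state is a closed-form fixed point.
The two inversion images combine into the bias-free ratio image

```
UNI = S₁·S₂ / (S₁² + S₂²)  ∈  [−0.5, 0.5]
```

which is insensitive to M0, T2* (for matched first echoes) and the receive
field, and is inverted to T1 through a dense lookup over (T1, relative B1).
T2* comes from a signal-weighted log-linear mono-exponential fit of the
second-block echoes at TE 3/11.5/20/28.5 ms.

## Worked example

```python
import mp2rageme as m

p = m.load_protocol("mp2rageme")          # bundled 7 T protocol
wm = m.SIM_TISSUES["wm"]                  # T1 1.15 s, T2* 26.7 ms

sig = m.simulate_cycle(p, wm)
print(sig.uni)                            # 0.05519727377376641

lut = m.build_lookup(p)
t1, valid = lut.invert(sig.uni)
print(t1)                                 # 1.1500000000000004

print(m.apparent_t1(p, 1.15, 1.2, lut)[0])  # 1.037262704906842
print(m.snr_ratio(6, 12, 31.4, 1.15))       # 0.7510226563793918
```

A white-matter voxel at nominal transmit field gives UNI ≈ 0.055, which the
lookup decodes back to exactly 1.150 s.  The same voxel acquired at 1.2×
the nominal field but decoded through the nominal table appears as 1.037 s —
the transmit-field bias the separately acquired B1 map corrects.  Reading
out at 6° instead of the 12° Ernst angle costs ~25% signal in white matter.

The same functionality is exposed on the command line:

```text
$ mp2rageme simulate --t1 1.15
s1 = +0.00416   s2 = +0.07509, +0.05462, +0.03973, +0.02889
UNI = +0.0552
Scan duration: 16:28 (987.84 s)
Dead time: 16.1% total gaps, 7.6% tail recovery

$ mp2rageme psf-sim --background wm --out psf.csv
blur_pct = 5.11 % of the GM-WM UNI difference
```

Other subcommands: `phantom` (synthetic acquisition as NIfTI), `lookup`,
`fit` (YAML-config pipeline producing T1/T2* maps, ROI CSV and a JSON
report), `b1-sim`, and `report` (Bland–Altman agreement between two maps).

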