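# MP2RAGEME 7 T protocol: single-echo first inversion, four-echo second
# inversion, 0.64 mm isotropic.  TIs are at the block centers.
kind: mp2rageme
name: mp2rageme
tr_cycle: 6.72        # s, time between inversions
tr_block1: 6.2        # ms
tr_block2: 31.4       # ms
te1: 3.0              # ms
te2: [3.0, 11.5, 20.0, 28.5]   # ms
ti1: 670.0            # ms
ti2: 3855.0           # ms
alpha1: 7.0           # deg
alpha2: 6.0           # deg
n_lines: 150
n_readouts: 147
inv_efficiency: 1.0
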