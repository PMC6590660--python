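# Reference single-echo MP2RAGE protocol acquired for comparison.
kind: mp2rage
name: mp2rage
tr_cycle: 6.0
tr_block1: 6.2
tr_block2: 6.2
te1: 3.0
te2: [3.0]
ti1: 1000.0
ti2: 3200.0
alpha1: 7.0
alpha2: 6.0
n_lines: 150
n_readouts: 147
inv_efficiency: 1.0
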