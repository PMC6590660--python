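# Reference multi-echo spoiled GRE (FLASH) protocol at the Ernst angle.
kind: megre
name: megre
tr: 31.4              # ms
alpha: 12.0           # deg
tes: [3.0, 11.5, 20.0, 28.5]   # ms
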