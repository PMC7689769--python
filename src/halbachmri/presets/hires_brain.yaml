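# Higher-resolution brain TSE (2 x 2 x 4 mm)
fov: [256, 256, 256]
matrix: [64, 128, 128]
tr: 500
te: 20
etl: 4
bandwidth: 20000
ordering: center_out
elliptical: true
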