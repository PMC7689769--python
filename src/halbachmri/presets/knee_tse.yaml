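# 3-D T1-weighted TSE knee protocol; full (non-elliptical) phase encoding
fov: [256, 256, 256]
matrix: [128, 128, 128]
tr: 130
te: 10
etl: 3
bandwidth: 20000
ordering: center_out
elliptical: false
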