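# T2-weighted 3-D TSE brain protocol (bright CSF, long effective TE)
fov: [160, 192, 256]
matrix: [40, 48, 64]
tr: 3000
te: 20
etl: 40
bandwidth: 20000
ordering: linear_low_high
elliptical: true
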