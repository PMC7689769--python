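# 2-D spin-echo projection protocol for the tube-grid phantom
fov: [256, 256]
matrix: [128, 128]
tr: 6000
te: 100
etl: 1
bandwidth: 20000
ordering: linear_low_high
elliptical: false
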