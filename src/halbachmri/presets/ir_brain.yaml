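# Inversion-recovery 3-D TSE brain protocol
fov: [160, 192, 256]
matrix: [40, 48, 64]
ti: 100
tr: 3000
te: 20
etl: 40
bandwidth: 20000
ordering: center_out
elliptical: true
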