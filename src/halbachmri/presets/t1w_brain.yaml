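# T1-weighted 3-D TSE brain protocol (rapid anatomical scan, CSF dark)
fov: [192, 192, 256]        # mm: readout, phase1, phase2
matrix: [48, 48, 64]
tr: 500                     # ms
te: 10                      # ms echo spacing
etl: 6
bandwidth: 20000            # Hz
ordering: center_out
elliptical: true
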