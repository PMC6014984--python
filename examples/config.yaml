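design: design.yaml
profiles: profiles.yaml
rates: rates.yaml
cells_per_sensor: 20000
coculture_cells: 10000
ebfp2_threshold: 300.0
mkate2_threshold: 100.0
seed: 1
outdir: mirsensor_out
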