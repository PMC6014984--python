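# Reporter kinetics (per hour); mRNA half-life ~3.5 h, protein ~23 h.
k_trs: 2.0
k_tln_ebfp2: 100.0
k_tln_mkate2: 100.0
delta_m: 0.2
delta_p: 0.03
k_cat: 1.0
calib:
  ebfp2: {gain: 1.0e-3, background: 5.0}
  mkate2: {gain: 1.0e-3, background: 5.0}
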