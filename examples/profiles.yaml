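# Two cell lines: the marker-positive target line has low activity for all
# sensed miRNAs; the off-target line has high activity (M/K_m up to 20).
- name: target_line
  lineage_marker_on: true
  activities:
    - {mirna_id: miR-21, M: 600, K_m: 6000}
    - {mirna_id: miR-23a, M: 600, K_m: 6000}
    - {mirna_id: miR-106b, M: 600, K_m: 6000}
- name: off_line
  lineage_marker_on: false
  activities:
    - {mirna_id: miR-21, M: 600, K_m: 30}
    - {mirna_id: miR-23a, M: 600, K_m: 60}
    - {mirna_id: miR-106b, M: 600, K_m: 100}
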