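# 3-input classifier: strongest target set in the 5' UTR, two in the 3' UTR
label: demo_classifier
inputs:
  - {mirna_id: miR-21, utr_position: five_prime}
  - {mirna_id: miR-23a, utr_position: three_prime}
  - {mirna_id: miR-106b, utr_position: three_prime}
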