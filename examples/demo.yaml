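# Demo plate: an untreated culture vs three drug-exposure windows of a
# fully inhibitory fusion blocker, 3 wells each, imaged daily from day 3.
n_wells: 3
n_fields: 1
days: [3, 4, 5, 6, 7, 8, 9, 10]
params:
  width: 384
  height: 384
  fusion_rate: 0.5
  f_max: 0.6
conditions:
  - name: ND
    schedule: ND
  - name: continuous
    schedule: continuous
    drug_effect: 0.0
  - name: early
    schedule: early
    drug_effect: 0.0
  - name: late
    schedule: late
    drug_effect: 0.0
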