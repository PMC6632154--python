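# Demo analysis: simulate the default scenario and run the full pipeline.
# Usage: adprev run --config configs/demo.yaml --out demo_out --seed 1
seed: 1
simulate:
  n: 8000
ages: {start: 60, stop: 90}
jackknife: {groups: 10}
comparisons:
  - [A_plus, male, A_plus, female]
  - [MCI_or_dementia, male, MCI_or_dementia, female]
  - [A_plus_T_minus, male, A_plus_T_plus, male]
sensitivity:
  tau_rois: [entorhinal, inferior_temporal, lateral_parietal]
  cu_fraction_deltas: [0.10, -0.10]
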