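{
 "name": "reference_multi_pld",
 "plds_s": [
  0.25,
  0.5,
  0.75,
  1.0,
  1.25,
  1.5
 ],
 "n_averages": 7,
 "label_duration_s": 1.4,
 "readout_duration_s": 1.275,
 "slice_duration_s": 0.053125,
 "n_slices": 5,
 "scan_time_budget_s": 300.0
}
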