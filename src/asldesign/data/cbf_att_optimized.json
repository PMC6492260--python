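{
 "name": "cbf_att_optimized",
 "plds_s": [
  0.2,
  0.2,
  0.225,
  0.3,
  0.375,
  0.45,
  0.5,
  0.55,
  0.6,
  0.6,
  0.625,
  0.625,
  0.65,
  0.65,
  0.675,
  0.675,
  0.7,
  0.7,
  0.7,
  0.7,
  1.25,
  1.275,
  1.3,
  1.35,
  1.375,
  1.4,
  1.425,
  1.425,
  1.475,
  1.5,
  1.675,
  1.75,
  1.8,
  1.825,
  1.85,
  1.875,
  1.9,
  1.925,
  1.95,
  1.975
 ],
 "n_averages": 1,
 "label_duration_s": 1.4,
 "readout_duration_s": 1.275,
 "slice_duration_s": 0.053125,
 "n_slices": 5,
 "scan_time_budget_s": 300.0
}
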