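{
 "name": "cbf_optimized",
 "plds_s": [
  0.2,
  0.7,
  0.825,
  1.0,
  1.125,
  1.25,
  1.325,
  1.4,
  1.475,
  1.55,
  1.625,
  1.675,
  1.7,
  1.725,
  1.75,
  1.775,
  1.8,
  1.825,
  1.85,
  1.85,
  1.875,
  1.875,
  1.9,
  1.925,
  1.925,
  1.95,
  1.975,
  1.975,
  2.0,
  2.025,
  2.025,
  2.05,
  2.075,
  2.075
 ],
 "n_averages": 1,
 "label_duration_s": 1.4,
 "readout_duration_s": 1.275,
 "slice_duration_s": 0.053125,
 "n_slices": 5,
 "scan_time_budget_s": 300.0
}
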