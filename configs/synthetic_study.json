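{
  "subjects": ["aa", "al", "av", "aw", "ay"],
  "channel_subsets": ["19", "30", "61", "118"],
  "kernels": ["linear", "rbf"],
  "roi_pool": null,
  "n_extras": 4,
  "n_pairs": 3,
  "filter_spec": {"band": [8.0, 13.0], "order": 4, "zero_phase": true},
  "analysis_window": [0.5, 2.5],
  "reg_lambda": 0.1111111111111111,
  "split_scheme": "table1",
  "selection": "test",
  "svm_C": 1.0,
  "sources_per_patch": 6,
  "seed": 0,
  "generator": {
    "n_trials_per_class": 140,
    "fs": 100.0,
    "trial_length": 3.5,
    "mu_freq": 10.0,
    "erd_attenuation": 0.4,
    "snr": 5.0,
    "n_background_sources": 50,
    "seed": 0
  }
}
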