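{
  "out_dir": "demo_output",
  "method": "tm",
  "simulation": {
    "n_participants": 20,
    "n_gray": 1500,
    "n_networks": 8,
    "jitter_sigma_mm": 3.0,
    "snr": 4.0,
    "n_frames": 750,
    "master_seed": 7
  },
  "minutes": null,
  "min_cluster": 5,
  "split_half_n": 10,
  "seed": 7
}
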