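{
  "classification": {
    "burned_accuracy_pct": 100.0,
    "burned_correct": 5,
    "burned_total": 5,
    "n": 10,
    "overall_accuracy_pct": 100.0,
    "unburned_accuracy_pct": 100.0,
    "unburned_correct": 5,
    "unburned_total": 5
  },
  "cvs_agreement": {
    "fraction_within_10": 1.0,
    "fraction_within_30": 1.0,
    "n": 5
  },
  "detection": {
    "fn": 0,
    "fp": 0,
    "precision": 1.0,
    "recall": 1.0,
    "tp": 10
  },
  "n_classified": 10,
  "n_segments": 10,
  "params": {
    "cbh_bin": 0.25,
    "chm_cell": 0.1,
    "gli_threshold": 0.5,
    "height_percentile": 25.0,
    "hull_alpha": null,
    "ivf_voxel": 0.5,
    "match_dist": 2.0,
    "match_height_tol": 0.3,
    "min_area": 0.3,
    "min_height": 2.0,
    "plot_radius": 11.28,
    "sigma": 0.05,
    "slice": 0.1,
    "spar": 0.65
  },
  "scorch_height_regression": {
    "n": 5,
    "r_squared": 0.999,
    "rmse_m": 0.125,
    "slope": 0.982
  },
  "seed": 20240901
}
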