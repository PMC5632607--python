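{
  "description": "Reference synthetic scenario: 60x60 landscape, 6 correlated layers, 3 virtual species. Regenerate bit-identically with admkit.pipeline.run_study(seed, StudyConfig(**config)) or `admkit simulate --config fixtures/scenario.yml --seed 60601`.",
  "seed": 60601,
  "config": {
    "n_layers": 6,
    "n_rows": 60,
    "n_cols": 60,
    "autocorr_range": 5.0,
    "n_latent": 3,
    "idiosyncratic": 0.35,
    "cell_size": 1000.0,
    "species_names": ["sp1", "sp2", "sp3"],
    "marginality_targets": [1.0, 1.2, 1.5],
    "tolerance_targets": [0.5, 0.5, 0.5],
    "n_museum": [120, 120, 120],
    "n_classes": 4,
    "patch_scale": 4.0,
    "subcell_ratio": 4,
    "n_sites": 30,
    "points_per_site": 30,
    "min_point_spacing": 200.0,
    "detection_prob": 0.8,
    "buffer_radius": 1000.0
  }
}
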