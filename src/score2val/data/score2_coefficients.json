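{
  "score2": {
    "comment": "SCORE2 (2021) 10-year fatal+non-fatal CVD risk model: sex-specific Fine-Gray log-subdistribution-hazard ratios on centred/scaled predictors, 10-year baseline survival, and the four region recalibration scale pairs. Transcribed configuration data; treated as data, not code.",
    "version": "2021",
    "male": {
      "terms": [
        {"name": "age", "variable": "age", "center": 60.0, "scale": 5.0, "interacts_with_age": false, "beta": 0.3742},
        {"name": "smoking", "variable": "smoking", "center": 0.0, "scale": 1.0, "interacts_with_age": false, "beta": 0.6012},
        {"name": "sbp", "variable": "sbp", "center": 120.0, "scale": 20.0, "interacts_with_age": false, "beta": 0.2777},
        {"name": "tchol", "variable": "tchol", "center": 6.0, "scale": 1.0, "interacts_with_age": false, "beta": 0.1458},
        {"name": "hdl", "variable": "hdl", "center": 1.3, "scale": 0.5, "interacts_with_age": false, "beta": -0.2698},
        {"name": "smoking_x_age", "variable": "smoking", "center": 0.0, "scale": 1.0, "interacts_with_age": true, "beta": -0.0755},
        {"name": "sbp_x_age", "variable": "sbp", "center": 120.0, "scale": 20.0, "interacts_with_age": true, "beta": -0.0255},
        {"name": "tchol_x_age", "variable": "tchol", "center": 6.0, "scale": 1.0, "interacts_with_age": true, "beta": -0.0281},
        {"name": "hdl_x_age", "variable": "hdl", "center": 1.3, "scale": 0.5, "interacts_with_age": true, "beta": 0.0426}
      ],
      "s0_10": 0.9605,
      "scales": {
        "low": [-0.5699, 0.7476],
        "moderate": [-0.1565, 0.8009],
        "high": [0.3207, 0.936],
        "very_high": [0.5836, 0.8294]
      }
    },
    "female": {
      "terms": [
        {"name": "age", "variable": "age", "center": 60.0, "scale": 5.0, "interacts_with_age": false, "beta": 0.4648},
        {"name": "smoking", "variable": "smoking", "center": 0.0, "scale": 1.0, "interacts_with_age": false, "beta": 0.7744},
        {"name": "sbp", "variable": "sbp", "center": 120.0, "scale": 20.0, "interacts_with_age": false, "beta": 0.3131},
        {"name": "tchol", "variable": "tchol", "center": 6.0, "scale": 1.0, "interacts_with_age": false, "beta": 0.1002},
        {"name": "hdl", "variable": "hdl", "center": 1.3, "scale": 0.5, "interacts_with_age": false, "beta": -0.2606},
        {"name": "smoking_x_age", "variable": "smoking", "center": 0.0, "scale": 1.0, "interacts_with_age": true, "beta": -0.1088},
        {"name": "sbp_x_age", "variable": "sbp", "center": 120.0, "scale": 20.0, "interacts_with_age": true, "beta": -0.0277},
        {"name": "tchol_x_age", "variable": "tchol", "center": 6.0, "scale": 1.0, "interacts_with_age": true, "beta": -0.0226},
        {"name": "hdl_x_age", "variable": "hdl", "center": 1.3, "scale": 0.5, "interacts_with_age": true, "beta": 0.0613}
      ],
      "s0_10": 0.9776,
      "scales": {
        "low": [-0.738, 0.7019],
        "moderate": [-0.3143, 0.7701],
        "high": [0.571, 0.9369],
        "very_high": [0.9412, 0.8329]
      }
    }
  }
}
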