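{
 "n_lv": 9,
 "x_mean": null,
 "y_mean": 0.0,
 "x_scale": null,
 "weights": null,
 "x_loadings": null,
 "y_loadings": null,
 "coefficients": [484.65, -1018.89, -887.77, 304.06, 1645.31, 354.86, 1092.13, 449.62, -1997.31, -589.93, 1283.30],
 "intercept": -1126.19,
 "feature_names": ["704", "534", "673", "568", "505", "734", "524", "949", "446", "594", "452"],
 "mode": "regression",
 "metadata": {
  "model_id": "printed-11-wavelength-calibration",
  "note": "Published 11-wavelength shikimic-acid calibration equation, transcribed verbatim. The second term's band label was printed as 'X5343 nm'; it is recorded here as 534 nm, the only matching member of the published 13-wavelength SPA list (446, 452, 473, 505, 524, 534, 568, 594, 673, 704, 715, 734, 949 nm). This is an assumption, not a verified correction.",
  "response": "shikimic acid concentration (fresh-weight units)",
  "inputs": "reflectance at the 11 sensitive wavelengths (nm)"
 }
}
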