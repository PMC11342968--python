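{
  "m": 2,
  "W0": [
    [0.544, 0.141],
    [0.703, 0.821],
    [0.455, 0.552]
  ],
  "sigma": 0.053,
  "n_source": 0,
  "notes": "Energy-preserving spherical Gaussian stain color distribution estimated from Carolina Breast Cancer Study (CBCS) H&E tissue microarray images; columns are hematoxylin, eosin in OD space."
}
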