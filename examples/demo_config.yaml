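# Demo run: simulate the three calibrated agonist classes at their
# emulated sample sizes, detect and featurize transients, apply the
# responder filter, and run group statistics + classification.
#
#   nodoscope run examples/demo_config.yaml --out runs/demo
seed: 7
simulate:
  classes: [capsaicin, glutamate, aitc]
transients:
  k_sd: 3.0
  artifact_fraction: 0.30
  artifact_window: 1.0
responders:
  post_window: 100.0
  exclusion_ratio: 0.5
analyze:
  features: [amplitude_dff, duration_s, n_peaks, integral_dff_s]
  folds: 10
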