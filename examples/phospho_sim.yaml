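# spbkit phospho simulate --config examples/phospho_sim.yaml --seed 1 --out sim_data
params:
  n_events: 2000
  frac_hp_sensitive: 0.5            # ~half of annotated CDK events
  frac_rescued_within_sensitive: 0.2  # about one fifth of HP-sensitive sites
  rescue_effect: 1.5                # multiplier on the tethered-strain peak
  noise_cv: 0.1                     # reporter-ion CV
  channel_mixing_range: 0.1         # +/-10% per-channel loading bias
  n_decoys: 50
  n_contaminants: 20
  loc_prob_below_frac: 0.1
  protein_drift_sd: 0.1
  timepoints_minutes: [0, 15, 30, 45, 60]
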