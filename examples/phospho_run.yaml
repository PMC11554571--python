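# spbkit phospho run --config examples/phospho_run.yaml --seed 1 --out results
paths:
  sites: sim_data/sites.tsv
  proteins: sim_data/proteins.tsv
  design: sim_data/design.tsv
  annotations: sim_data/annotations.tsv
params:
  min_loc_prob: 0.7       # localization-probability filter (inclusive)
  rescue_threshold: 1.2   # max phosphorylation ratio classifying rescue
  n_boot: 10000           # bootstrap resamples for trajectory CIs
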