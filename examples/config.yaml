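# Small end-to-end pipeline configuration for the hgmod CLI:
#   hgmod simulate -c examples/config.yaml
#   hgmod tf -c examples/config.yaml
#   hgmod analyze -c examples/config.yaml
#   hgmod compare -c examples/config.yaml
#   hgmod lmm -c examples/config.yaml
#   hgmod behavior -c examples/config.yaml
#   hgmod report -c examples/config.yaml
n_patients: 12   # the mixed model needs more patients than fixed terms
trials_per_type: 12
electrodes_per_roi:
  left:
    posterior_MFG: 15
    posterior_IFG: 10
effects:
  - roi: posterior_MFG
    hemisphere: left
    sentence_type: concrete_first
    anchor: p1_offset
    onset_lag_ms: 150.0
    offset_lag_ms: 450.0
    amplitude_change: 0.15
  - roi: posterior_MFG
    hemisphere: left
    sentence_type: wh_first
    anchor: p1_offset
    onset_lag_ms: 150.0
    offset_lag_ms: 450.0
    amplitude_change: -0.053
n_perm: 1000
n_boot: 1000
epoch_window: [-600.0, 3900.0]
seed_simulate: 1
seed_permutation: 2
seed_bootstrap: 3
out_dir: scratch/example_run
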