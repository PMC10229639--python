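# Demo pipeline configuration: three trap stiffnesses at 30 mM Pi with a
# pure Pi-induced (slip) detachment pathway.  Run with
#   trapforge run --config examples/demo_run.yaml
seed: 7
out_dir: scratch/demo_run
stages: [simulate, detect, features, table1, fit_bell]
conditions:
  - {label: S217A_pi30_k0.04, construct: S217A, pi_mM: 30.0, k_trap: 0.04, duration_s: 30.0}
  - {label: S217A_pi30_k0.06, construct: S217A, pi_mM: 30.0, k_trap: 0.06, duration_s: 30.0}
  - {label: S217A_pi30_k0.10, construct: S217A, pi_mM: 30.0, k_trap: 0.10, duration_s: 30.0}
sim_overrides:
  k_adp0: 0.0
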