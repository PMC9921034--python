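# Two-species-style contrast demo: one synthetic "selfing" landscape run.
# Swap the scenario block (e.g. fst_target 0.25, selfing 0.3) for the
# mixed-mating counterpart.
scenario:
  species: SpSelf
  n_sites: 4
  n_loci: 1500
  fst_target: 0.6
  inbreeding_f: 0.5
  selfing: [0.9, 0.8, 0.9, 0.7]
  epsilon: 0.005
  locus_missing_rate: 0.03
  fraction_multi_snp_clones: 0.1
  reproducibility_distribution: [uniform, 0.96, 1.0]
seed: 1
out_dir: demo_out
run_ml: true
cnn_enabled: false      # set true for the full per-site CNN stage
among_scheme:
  n_replicates: 50
  maf_thresholds: [0.01, 0.05]
germination:
  SpSelf: [94, 100]
  SpOut: [52, 100]
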