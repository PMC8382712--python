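# Full pipeline run on a simulated cohort.
# mcts-nucleus run --config examples/run.yaml
out_dir: scratch/demo-run
seed: 7
stages: [simulate, segment, features, cellcycle, spatial]

simulate:
  n_spheroids: 2
  phantom:
    spheroid_radius: 50.0
    n_nuclei: 110

segment:
  channel: dapi
  config:
    hmin_depth: 1.5
    gaussian_sigma: 0.35
  # replacements: seeds_fix.csv   # label,z,y,x rows replacing cluster seeds

features:
  channels: [dapi, rfp, gfp]
  volume_gate: [0.6, 1.8]

cellcycle:
  mode: threshold     # or: svm
  dna_channel: dapi

spatial:
  layer_width: 10.0
  max_depth: 60.0
  closing_radius: 10.0
  trend_bin: 5.0
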