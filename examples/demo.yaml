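# End-to-end demo: every stage on seeded synthetic data.
#   mtarray run --config examples/demo.yaml
seed: 7
stages: [orientation, motility, invitro, hydrodynamics, morphology]
out_dir: mtarray_demo_out
synth:
  n_encounters: 150
# thresholds use the standard scoring defaults:
#   displacement_um: 0.5     fast_nm_s: 700     paraxial_deg: 45
#   looping_deg: 90          min_coalign_um: 2  bundle_ratio: 3
#   bundle_len_um: 2.3
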