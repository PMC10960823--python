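# Demo pipeline configuration: a 64x64 synthetic scene, five annual maps.
# Run with:  wetmap run --config examples/demo_config.yaml
seed: 7
out_dir: scratch/demo_run
extent: [64, 64]
years: [2000, 2001, 2002, 2003, 2004]
dates_per_year: 12
cloud_fraction: 0.05
n_per_class: 40
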