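# Full-pipeline configuration for `icns run --config examples/run.yaml`.
outdir: icns_run
seed: 1
n_male: 2
n_female: 1
warp_amplitude: 300.0
k_min: 2
k_max: 16
n_null: 10
cluster_subsample: 800
roi_radius: 500.0
lambda_smooth: 1.0
write_plots: true
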