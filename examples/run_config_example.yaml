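# Example end-to-end run configuration for `sdqprofiles pipeline --config`.
scales: [emotional, conduct, hyperactivity, social, prosocial]
informants: [self, parent]
n_categories: 11
K_range: [1, 2, 3, 4, 5, 6, 7, 8]
n_starts: 20
start_iters: 30
tol: 1.0e-8
max_iter: 500
seed: 0
parameterization: adjacent
cutoff_file: examples/cutoffs_example.yaml
gender_threshold_pct: 20.0
min_group_n: 100
min_cell_size: 30
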