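# Desk-scale analysis grid for `thermoccupancy run --config examples/run.yaml`.
# Full-scale runs use n_peaks/n_nonpeaks of 1000.
modes: [single, cooperative, antagonistic, competition]
d_T_list: [30, 150]
n_peaks: 100
n_nonpeaks: 100
n_decoys: 8
n_shuffles: 100
seed: 7
out_dir: thermoccupancy_run
accessibility: correlated
spacing_segments: 100
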