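# Default pipeline configuration: peptide-evidence filtering, the
# observability window reconstructing a nanoLC-Orbitrap acquisition, and
# the candidate-selection thresholds.
expect_threshold: 0.05
top_n_d: 30
binder_threshold: 0.0
require_both_replicates: true
seed: 0
mz_min: 350.0
mz_max: 1800.0
charges: [2, 3]
min_length: 6
max_missed_cleavages: 2
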