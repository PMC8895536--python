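"""Empirical significance via chemical-replacement null classifiers.

Each MIE's active chemicals are swapped for random decoys (matched in
chemical count and per-chemical profile volume, never annotated to the
MIE), the classifier is retrained, and the empirical p-value is the
fraction of null accuracies at or above the original's.
"""

from miescreen import SimConfig, run_screen, simulate_dataset

dataset = simulate_dataset(SimConfig(seed=1))
res = run_screen(dataset.records, dataset.meta, dataset.matrix,
                 cell_line="MCF7like", algorithm="SVM_L",
                 n_null=25, seed=1)

cols = ["mie", "internal_accuracy", "mean_null_accuracy", "empirical_p"]
print(res.table[cols].round(3).to_string(index=False))

# Null accuracies hover near 0.55-0.65 (replicate profiles of the same
# chemical resemble each other even without a shared mechanism); a planted
# classifier at ~1.0 therefore gets empirical p = 0, i.e. none of the 25
# chemically-randomized nulls matched it.
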