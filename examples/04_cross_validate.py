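"""Cross-validate the pipeline on a synthetic planted-signal dataset.

A reduced-scale run (100 records per class, sequences up to 400 nt,
a 100-dimensional embedding) of the same protocol the package uses at full scale:
stratified 5-fold CV, the pipeline refit from scratch in every fold,
confusion counts pooled across folds.  Accuracy grows with dataset
size and sequence length; at full scale (340/342 records, 500 nt,
10 folds, 20 epochs) the same protocol exceeds 0.9.  Setting
enrichment=1 gives chance-level (~0.5) accuracy.
"""

from orivec import (
    CNNConfig,
    PipelineConfig,
    SkipGramConfig,
    SyntheticConfig,
    generate_dataset,
    kfold_cv,
)

ds = generate_dataset(
    SyntheticConfig(n_pos=100, n_neg=100, max_len=400, enrichment=3.0, seed=0)
)
print(f"dataset: {ds.n_pos} ORI + {ds.n_neg} non-ORI records")

cfg = PipelineConfig(
    segmentation="skip",
    mode="default",
    embedding=SkipGramConfig(dim=100, epochs=3, seed=0),
    cnn=CNNConfig(epochs=20, seed=0),
)
report = kfold_cv(ds, cfg, k=5, seed=0)
print("pooled 5-fold CV: ", report.summary())
print("\nper-fold confusion matrices (TP/TN/FP/FN):")
for i, cm in enumerate(report.fold_matrices):
    print(f"   fold {i}: {cm.tp:>2d} {cm.tn:>2d} {cm.fp:>2d} {cm.fn:>2d}")
# Acc/Sn/Sp near 1 and MCC near 1 mean the compositional signal is
# recovered; AUC close to 1 means the score ranks almost every
# positive above every negative.
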