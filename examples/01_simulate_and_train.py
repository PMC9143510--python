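"""Simulate a case/control cohort and train the classifier on it.

Generates a 40-sample cohort with 5 informative species, runs the full
pipeline (species filter at 0.03 %, CSS normalisation, 15 % stratified
test split) with a configuration that converges on a cohort this small,
and prints the held-out metrics.
"""

from phenodeep import (
    NetworkConfig,
    PreprocessConfig,
    SynthConfig,
    generate,
    train_pipeline,
)

cfg = SynthConfig(n_per_class=[20, 20], n_taxa=50, n_informative=5,
                  log_fold_change=3.0, seed=0)
table, meta, informative = generate(cfg)
print(f"cohort: {table.n_samples} samples x {table.n_taxa} species, "
      f"{len(informative)} informative")

pre = PreprocessConfig(test_fraction=0.25, validation_fraction=0.0, seed=0)
net = NetworkConfig(n_layers=2, n_neurons=16, learning_rate=1e-3,
                    epochs=30, dropout_enabled=False, seed=0)
result = train_pipeline(table, meta, pre, net)

rep = result.report
print(f"held-out accuracy {rep.accuracy:.3f}, AUC {rep.auc:.3f}, "
      f"precision {rep.precision:.3f}, F1 {rep.f1:.3f}")
print("confusion (rows = true class):")
print(rep.confusion)
# Accuracy near 1 means the network recovered the informative taxa's
# multiplicative shift; AUC measures the same thing threshold-free.
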