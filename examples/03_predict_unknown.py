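"""Save a trained model, reload it, and classify unlabeled samples.

The archive carries the retained taxon list, the CSS normalisation state
and the label encoding, so a new profile is projected into exactly the
training-time feature space (novel taxa ignored, missing taxa zero).
"""

import tempfile
from pathlib import Path

from phenodeep import (
    NetworkConfig,
    PreprocessConfig,
    SynthConfig,
    generate,
    load_model,
    predict_samples,
    save_model,
    train_pipeline,
)

train_cohort, meta, _ = generate(SynthConfig(n_per_class=[20, 20], n_taxa=50,
                                             n_informative=5, seed=2))
result = train_pipeline(
    train_cohort, meta,
    PreprocessConfig(seed=2),
    NetworkConfig(n_layers=2, n_neurons=16, learning_rate=1e-3, epochs=30,
                  dropout_enabled=False, seed=2),
)

path = Path(tempfile.mkdtemp()) / "model.zip"
save_model(result.model, path)
model = load_model(path)
print(f"archive: {path.stat().st_size} bytes, "
      f"{len(model.retained_taxa)} retained taxa, labels {model.label_order}")

# "unknown" samples: a fresh draw from the same population, labels withheld
unknown, truth, _ = generate(SynthConfig(n_per_class=[5, 5], n_taxa=50,
                                         n_informative=5, seed=99))
labels, proba, sample_ids = predict_samples(model, unknown)
correct = 0
for sid, lab, row in zip(sample_ids, labels, proba):
    ok = lab == truth.mapping[sid]
    correct += ok
    print(f"{sid}: predicted {lab} (p={row.max():.3f}) "
          f"{'==' if ok else '!='} true {truth.mapping[sid]}")
print(f"{correct}/{len(labels)} correct on unseen samples")
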