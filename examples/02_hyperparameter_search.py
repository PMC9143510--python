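"""Randomized hyperparameter search with early stopping.

Draws network configurations from the bounded ranges (layers/neurons 5-75,
dropout rate 0.1-0.9, learning rate 5e-6 to 5e-4 log-uniform, weight decay
0-0.1), scores each by validation accuracy, and stops once 10 consecutive
draws fail to improve.
"""

from phenodeep import (
    NetworkConfig,
    PreprocessConfig,
    SynthConfig,
    generate,
    train_pipeline,
)
from phenodeep.search import SearchSpace, random_search

table, meta, _ = generate(SynthConfig(n_per_class=[20, 20], n_taxa=50,
                                      n_informative=5, seed=1))
pre = PreprocessConfig(seed=1)
base = NetworkConfig(epochs=30, seed=1)


def evaluator(cfg):
    res = train_pipeline(table, meta, pre, cfg)
    return res.history.epochs[res.history.best_epoch].validation_accuracy or 0.0


result = random_search(SearchSpace(), max_iterations=10, patience=10,
                       seed=1, base_config=base, evaluator=evaluator)

for i, trial in enumerate(result.trials):
    c = trial.config
    print(f"trial {i}: layers={c.n_layers:2d} neurons={c.n_neurons:2d} "
          f"lr={c.learning_rate:.2e} wd={c.weight_decay:.3f} "
          f"dropout={c.dropout_rate if c.dropout_enabled else 'off'} "
          f"-> val acc {trial.validation_accuracy:.3f}")
print(f"best: trial {result.best_trial}, stopped early: {result.stopped_early}")
# The winning configuration is then retrained and evaluated on the test
# partition exactly like a hand-chosen one.
final = train_pipeline(table, meta, pre, result.best_config)
print(f"test accuracy of best config: {final.report.accuracy:.3f}")
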