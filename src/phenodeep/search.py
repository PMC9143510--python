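"""Randomized hyperparameter search with validation-accuracy early stopping.

Configurations are drawn uniformly from bounded ranges (log-uniformly for
the learning rate, which spans two orders of magnitude); the search stops
after ``patience`` consecutive draws fail to strictly improve the running
best validation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DivergedError, SearchError
from .model import NetworkConfig, build_network, train

__all__ = ["SearchSpace", "Trial", "SearchResult", "sample_config", "random_search"]


@dataclass
class SearchSpace:
    """Inclusive sampling ranges for the tunable hyperparameters."""

    n_layers: tuple[int, int] = (5, 75)
    n_neurons: tuple[int, int] = (5, 75)
    dropout_enabled: tuple[bool, ...] = (True, False)
    dropout_rate: tuple[float, float] = (0.1, 0.9)
    learning_rate: tuple[float, float] = (0.000005, 0.0005)
    weight_decay: tuple[float, float] = (0.0, 0.1)

    def __post_init__(self) -> None:
        for name in ("n_layers", "n_neurons", "dropout_rate", "learning_rate", "weight_decay"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SearchError(f"empty range for {name}: ({lo}, {hi})")
        if not self.dropout_enabled:
            raise SearchError("dropout_enabled choices must be non-empty")


def sample_config(
    space: SearchSpace,
    rng: np.random.Generator,
    base: NetworkConfig | None = None,
) -> NetworkConfig:
    """Draw one configuration from the space.

    Integer ranges are uniform inclusive; ``learning_rate`` is log-uniform;
    ``dropout_rate`` is drawn only when the dropout coin lands on enabled
    (otherwise the base default is kept).  Non-searched fields (batch size,
    epochs, seed) keep the base configuration's values.
    """
    base = base or NetworkConfig()
    n_layers = int(rng.integers(space.n_layers[0], space.n_layers[1] + 1))
    n_neurons = int(rng.integers(space.n_neurons[0], space.n_neurons[1] + 1))
    dropout_enabled = bool(space.dropout_enabled[rng.integers(len(space.dropout_enabled))])
    if dropout_enabled:
        dropout_rate = float(rng.uniform(*space.dropout_rate))
    else:
        dropout_rate = base.dropout_rate
    lo, hi = space.learning_rate
    learning_rate = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    weight_decay = float(rng.uniform(*space.weight_decay))
    return replace(
        base,
        n_layers=n_layers,
        n_neurons=n_neurons,
        dropout_enabled=dropout_enabled,
        dropout_rate=dropout_rate,
        learning_rate=learning_rate,
        weight_decay=weight_decay,
    )


@dataclass
class Trial:
    config: NetworkConfig
    validation_accuracy: float
    diverged: bool = False


@dataclass
class SearchResult:
    trials: list[Trial] = field(default_factory=list)
    best_trial: int = 0
    stopped_early: bool = False

    @property
    def iterations_run(self) -> int:
        return len(self.trials)

    @property
    def best_config(self) -> NetworkConfig:
        return self.trials[self.best_trial].config


def random_search(
    space: SearchSpace,
    train_features=None,
    train_labels=None,
    val_features=None,
    val_labels=None,
    *,
    max_iterations: int,
    patience: int = 10,
    seed: int = 0,
    base_config: NetworkConfig | None = None,
    evaluator=None,
) -> SearchResult:
    """Evaluate randomly drawn configurations; keep the best.

    Each trial trains a fresh network (trial ``i`` uses seed ``seed + i``)
    and is scored by its best validation accuracy.  A trial whose training
    diverges is recorded with accuracy 0 and the search continues; if every
    trial diverges the search errors out.  ``evaluator`` may replace the
    default train-and-score procedure (e.g. in tests).
    """
    if max_iterations < 1:
        raise SearchError("max_iterations must be >= 1")
    if patience < 1:
        raise SearchError("patience must be >= 1")
    if evaluator is None:
        if train_features is None or val_features is None or len(val_features) == 0:
            raise SearchError("random_search needs training and validation data")
        n_features = np.asarray(train_features).shape[1]
        n_classes = int(max(np.max(train_labels), np.max(val_labels))) + 1

        def evaluator(cfg: NetworkConfig) -> float:
            net = build_network(cfg, n_features, n_classes)
            _, history = train(
                net, train_features, train_labels, val_features, val_labels, cfg
            )
            return history.epochs[history.best_epoch].validation_accuracy

    rng = np.random.default_rng(seed)
    result = SearchResult()
    best = -np.inf
    fails = 0
    for i in range(max_iterations):
        cfg = sample_config(space, rng, base_config)
        cfg = replace(cfg, seed=seed + i)
        try:
            acc = float(evaluator(cfg))
            diverged = False
        except DivergedError:
            acc = 0.0
            diverged = True
        result.trials.append(Trial(cfg, acc, diverged))
        if acc > best:
            best = acc
            result.best_trial = i
            fails = 0
        else:
            fails += 1
            if fails >= patience:
                result.stopped_early = True
                break
    if all(t.diverged for t in result.trials):
        raise SearchError("all search trials diverged")
    return result
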