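"""The deep feedforward classifier: build, train, persist, predict.

Architecture: ``n_layers`` hidden linear layers of width ``n_neurons``, each
followed by an ELU activation and (optionally) an inverted-dropout layer,
then a final linear layer to ``n_classes`` logits.  Softmax is a
prediction-time view; the training loss is cross-entropy computed from raw
logits through a fused log-softmax.  Optimisation is Adam with L2 weight
decay, mini-batches of ``batch_size``, per-epoch reshuffling from a seeded
generator.

Initialisation policy: hidden weights are He-normal, biases zero, and the
output layer starts at exactly zero so the untrained network predicts the
uniform distribution and early decisions are driven by learned signal rather
than random output weights.
"""

from __future__ import annotations

import io as _io
import json
import os
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import DivergedError, ModelArchiveError, PhenodeepError
from .preprocess import NormalizationState

__all__ = [
    "NetworkConfig",
    "FeedForwardNetwork",
    "TrainedModel",
    "TrainingHistory",
    "EpochRecord",
    "build_network",
    "train",
    "predict_proba",
    "predict_label",
    "save_model",
    "load_model",
]

FORMAT_VERSION = "1"


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    ``n_layers`` counts hidden linear layers; the output layer is additional.
    """

    n_layers: int = 10
    n_neurons: int = 25
    dropout_enabled: bool = True
    dropout_rate: float = 0.5
    learning_rate: float = 0.00003
    weight_decay: float = 0.0
    batch_size: int = 50
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise PhenodeepError("n_layers must be >= 1")
        if self.n_neurons < 1:
            raise PhenodeepError("n_neurons must be >= 1")
        if not 0 < self.dropout_rate < 1:
            raise PhenodeepError("dropout_rate must be in (0, 1)")
        if self.learning_rate <= 0:
            raise PhenodeepError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise PhenodeepError("weight_decay must be >= 0")
        if self.batch_size < 1:
            raise PhenodeepError("batch_size must be >= 1")
        if self.epochs < 1:
            raise PhenodeepError("epochs must be >= 1")


def _elu(z: np.ndarray) -> np.ndarray:
    out = z.copy()
    neg = z < 0
    out[neg] = np.expm1(z[neg])
    return out


def _elu_grad(z: np.ndarray) -> np.ndarray:
    out = np.ones_like(z)
    neg = z < 0
    out[neg] = np.exp(z[neg])
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class FeedForwardNetwork:
    """Weights plus forward/backward passes for the ELU multilayer perceptron."""

    def __init__(self, config: NetworkConfig, n_features: int, n_classes: int):
        if n_features < 1:
            raise PhenodeepError("n_features must be >= 1")
        if n_classes < 2:
            raise PhenodeepError("n_classes must be >= 2")
        self.config = config
        self.n_features = n_features
        self.n_classes = n_classes
        rng = np.random.default_rng(config.seed)
        dims = [n_features] + [config.n_neurons] * config.n_layers + [n_classes]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for i in range(len(dims) - 1):
            fan_in, fan_out = dims[i], dims[i + 1]
            if i == len(dims) - 2:
                W = np.zeros((fan_in, fan_out))  # zero-init output layer
            else:
                W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.weights.append(W)
            self.biases.append(np.zeros(fan_out))
        self.adam_steps = 0  # number of optimizer updates performed

    # -- geometry --------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    # -- forward ---------------------------------------------------------
    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Return (logits, last_hidden, per-layer caches).

        Dropout is applied only when ``training`` is true and enabled in the
        config; masks are drawn from ``rng``.
        """
        cfg = self.config
        drop = cfg.dropout_rate if (training and cfg.dropout_enabled) else 0.0
        h = X
        caches = []
        for i in range(len(self.weights) - 1):
            z = h @ self.weights[i] + self.biases[i]
            a = _elu(z)
            if drop > 0.0:
                mask = (rng.random(a.shape) >= drop) / (1.0 - drop)
                out = a * mask
            else:
                mask = None
                out = a
            caches.append((h, z, mask))
            h = out
        logits = h @ self.weights[-1] + self.biases[-1]
        return logits, h, caches

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise PhenodeepError(
                f"feature width mismatch: expected {self.n_features}, "
                f"got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        logits, _, _ = self.forward(X, training=False)
        return logits

    # -- backward --------------------------------------------------------
    def backward(self, grad_logits: np.ndarray, last_hidden: np.ndarray, caches):
        """Gradients of the loss w.r.t. all weights and biases."""
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        gW[-1] = last_hidden.T @ grad_logits
        gb[-1] = grad_logits.sum(axis=0)
        d = grad_logits @ self.weights[-1].T
        for i in range(len(self.weights) - 2, -1, -1):
            h, z, mask = caches[i]
            if mask is not None:
                d = d * mask
            d = d * _elu_grad(z)
            gW[i] = h.T @ d
            gb[i] = d.sum(axis=0)
            if i > 0:
                d = d @ self.weights[i].T
        return gW, gb


class _Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, net: FeedForwardNetwork, lr: float, weight_decay: float):
        self.net = net
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.mW = [np.zeros_like(W) for W in net.weights]
        self.vW = [np.zeros_like(W) for W in net.weights]
        self.mb = [np.zeros_like(b) for b in net.biases]
        self.vb = [np.zeros_like(b) for b in net.biases]

    def step(self, gW, gb) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for i in range(len(self.net.weights)):
            g = gW[i] + self.wd * self.net.weights[i]
            self.mW[i] = self.b1 * self.mW[i] + (1 - self.b1) * g
            self.vW[i] = self.b2 * self.vW[i] + (1 - self.b2) * g * g
            self.net.weights[i] -= self.lr * (self.mW[i] / c1) / (
                np.sqrt(self.vW[i] / c2) + self.eps
            )
            g = gb[i] + self.wd * self.net.biases[i]
            self.mb[i] = self.b1 * self.mb[i] + (1 - self.b1) * g
            self.vb[i] = self.b2 * self.vb[i] + (1 - self.b2) * g * g
            self.net.biases[i] -= self.lr * (self.mb[i] / c1) / (
                np.sqrt(self.vb[i] / c2) + self.eps
            )
        self.net.adam_steps = self.t


@dataclass
class EpochRecord:
    train_loss: float
    train_accuracy: float
    validation_accuracy: float | None


@dataclass
class TrainingHistory:
    epochs: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = 0


@dataclass
class TrainedModel:
    """A trained network plus everything needed to replay preprocessing."""

    config: NetworkConfig
    network: FeedForwardNetwork
    retained_taxa: list[str] = field(default_factory=list)
    normalization: NormalizationState | None = None
    label_order: list[str] = field(default_factory=list)
    preprocess: dict | None = None

    @property
    def n_features(self) -> int:
        return self.network.n_features

    @property
    def n_classes(self) -> int:
        return self.network.n_classes


def build_network(config: NetworkConfig, n_features: int, n_classes: int) -> FeedForwardNetwork:
    """Construct an untrained network with seeded initial weights."""
    return FeedForwardNetwork(config, n_features, n_classes)


def _cross_entropy(logits: np.ndarray, y: np.ndarray) -> float:
    z = logits - logits.max(axis=1, keepdims=True)
    log_norm = np.log(np.exp(z).sum(axis=1))
    return float(np.mean(log_norm - z[np.arange(len(y)), y]))


def train(
    network: FeedForwardNetwork,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: np.ndarray | None,
    val_labels: np.ndarray | None,
    config: NetworkConfig | None = None,
) -> tuple[TrainedModel, TrainingHistory]:
    """Train with Adam on mini-batch cross-entropy.

    Returns the weights of the epoch with the best validation accuracy
    (ties -> earliest); with no validation set, the final epoch's weights.
    """
    cfg = config or network.config
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    if len(X) == 0:
        raise PhenodeepError("empty training set")
    if len(X) != len(y):
        raise PhenodeepError("train feature/label lengths differ")
    has_val = val_features is not None and len(val_features) > 0
    if has_val:
        Xv = np.asarray(val_features, dtype=float)
        yv = np.asarray(val_labels, dtype=int)

    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(network, cfg.learning_rate, cfg.weight_decay)
    history = TrainingHistory()
    best_val = -np.inf
    best_weights = None
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(X))
        losses = []
        sizes = []
        for start in range(0, len(X), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits, last_hidden, caches = network.forward(xb, training=True, rng=rng)
            loss = _cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise DivergedError(f"training diverged at epoch {epoch + 1}")
            P = _softmax(logits)
            G = P
            G[np.arange(len(yb)), yb] -= 1.0
            G /= len(yb)
            gW, gb = network.backward(G, last_hidden, caches)
            opt.step(gW, gb)
            losses.append(loss)
            sizes.append(len(yb))
        train_loss = float(np.average(losses, weights=sizes))
        train_acc = float(np.mean(network.predict_logits(X).argmax(axis=1) == y))
        if has_val:
            val_acc = float(np.mean(network.predict_logits(Xv).argmax(axis=1) == yv))
            if val_acc > best_val:
                best_val = val_acc
                best_weights = (
                    [W.copy() for W in network.weights],
                    [b.copy() for b in network.biases],
                )
                history.best_epoch = epoch
        else:
            val_acc = None
            history.best_epoch = epoch
        history.epochs.append(EpochRecord(train_loss, train_acc, val_acc))
    if has_val and best_weights is not None:
        network.weights = best_weights[0]
        network.biases = best_weights[1]
    return TrainedModel(config=cfg, network=network), history


def predict_proba(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Class-probability matrix (softmax over logits, dropout inactive)."""
    logits = model.network.predict_logits(features)
    return _softmax(logits)


def predict_label(model: TrainedModel, features: np.ndarray) -> list[str]:
    """Predicted labels; argmax ties break toward the lowest class index."""
    proba = predict_proba(model, features)
    idx = proba.argmax(axis=1)
    if model.label_order:
        return [model.label_order[i] for i in idx]
    return [str(i) for i in idx]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | os.PathLike) -> None:
    """Write a single zip archive; :func:`load_model` reproduces predictions
    bit-for-bit."""
    net = model.network
    buf = _io.BytesIO()
    arrays = {}
    for i, (W, b) in enumerate(zip(net.weights, net.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(buf, **arrays)
    config = {
        "network": asdict(model.config),
        "preprocess": model.preprocess,
        "n_features": net.n_features,
        "n_classes": net.n_classes,
    }
    norm = None
    if model.normalization is not None:
        norm = {
            "css_quantile": model.normalization.css_quantile,
            "reference_scale": model.normalization.reference_scale,
            "per_sample_factors": model.normalization.per_sample_factors,
        }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("format_version", FORMAT_VERSION)
        zf.writestr("config.json", json.dumps(config, indent=1))
        zf.writestr("labels.json", json.dumps({"label_order": model.label_order}))
        zf.writestr("taxa.txt", "\n".join(model.retained_taxa))
        zf.writestr("normalization.json", json.dumps(norm))
        zf.writestr("weights.bin", buf.getvalue())


def load_model(path: str | os.PathLike) -> TrainedModel:
    """Load a model archive written by :func:`save_model`."""
    try:
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            required = {
                "format_version",
                "config.json",
                "labels.json",
                "taxa.txt",
                "normalization.json",
                "weights.bin",
            }
            missing = required - names
            if missing:
                raise ModelArchiveError(
                    f"{path}: corrupted archive, missing members {sorted(missing)}"
                )
            version = zf.read("format_version").decode()
            if version != FORMAT_VERSION:
                raise ModelArchiveError(
                    f"{path}: unsupported format version {version!r} "
                    f"(expected {FORMAT_VERSION!r})"
                )
            config = json.loads(zf.read("config.json"))
            labels = json.loads(zf.read("labels.json"))
            taxa_text = zf.read("taxa.txt").decode()
            norm = json.loads(zf.read("normalization.json"))
            weights = np.load(_io.BytesIO(zf.read("weights.bin")))
    except (zipfile.BadZipFile, OSError, ValueError, KeyError) as exc:
        raise ModelArchiveError(f"{path}: not a readable model archive ({exc})") from exc
    net_cfg = NetworkConfig(**config["network"])
    net = FeedForwardNetwork(net_cfg, config["n_features"], config["n_classes"])
    try:
        net.weights = [np.array(weights[f"W{i}"]) for i in range(len(net.weights))]
        net.biases = [np.array(weights[f"b{i}"]) for i in range(len(net.biases))]
    except KeyError as exc:
        raise ModelArchiveError(f"{path}: weight arrays missing ({exc})") from exc
    state = None
    if norm is not None:
        state = NormalizationState(
            norm["css_quantile"], norm["reference_scale"], norm["per_sample_factors"]
        )
    retained = [t for t in taxa_text.splitlines() if t]
    return TrainedModel(
        config=net_cfg,
        network=net,
        retained_taxa=retained,
        normalization=state,
        label_order=labels["label_order"],
        preprocess=config.get("preprocess"),
    )
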