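import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from phenodeep import (
    DivergedError,
    ModelArchiveError,
    NetworkConfig,
    PhenodeepError,
    build_network,
    load_model,
    predict_label,
    predict_proba,
    save_model,
    train,
)
from phenodeep.model import TrainedModel, _cross_entropy


def _separable(n=60, f=10, seed=0, gap=4.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, f))
    y = (rng.random(n) < 0.5).astype(int)
    X[:, 0] += gap * y
    return X, y


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def test_parameter_count_closed_form():
    """(in+1)*out summed over layers: 3 hidden layers of 10 on 50 features,
    2 classes -> 510 + 110 + 110 + 22 = 752."""
    net = build_network(NetworkConfig(n_layers=3, n_neurons=10), 50, 2)
    assert net.n_parameters == 752


def test_single_hidden_layer_shapes():
    net = build_network(NetworkConfig(n_layers=1, n_neurons=7), 5, 3)
    assert [W.shape for W in net.weights] == [(5, 7), (7, 3)]


def test_seeded_init_reproducible():
    cfg = NetworkConfig(n_layers=2, seed=9)
    a = build_network(cfg, 8, 2)
    b = build_network(cfg, 8, 2)
    for Wa, Wb in zip(a.weights, b.weights):
        np.testing.assert_array_equal(Wa, Wb)


def test_too_few_classes_rejected():
    with pytest.raises(PhenodeepError):
        build_network(NetworkConfig(), 5, 1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_training_deterministic():
    X, y = _separable()
    cfg = NetworkConfig(n_layers=2, n_neurons=8, epochs=3, seed=4)
    runs = []
    for _ in range(2):
        net = build_network(cfg, X.shape[1], 2)
        _, hist = train(net, X, y, X[:10], y[:10], cfg)
        runs.append([(r.train_loss, r.train_accuracy, r.validation_accuracy) for r in hist.epochs])
    assert runs[0] == runs[1]


def test_one_step_per_epoch_when_batch_covers_all():
    X, y = _separable(n=30)
    cfg = NetworkConfig(n_layers=1, epochs=1, batch_size=64, seed=0)
    net = build_network(cfg, X.shape[1], 2)
    train(net, X, y, None, None, cfg)
    assert net.adam_steps == 1


def test_learns_separable_data():
    """With enough effective optimisation (higher learning rate) the network
    drives training accuracy to >= 0.95 on linearly separable data, matching
    what a linear classifier achieves."""
    X, y = _separable(n=120, seed=1, gap=8.0)
    oracle = LogisticRegression(max_iter=1000).fit(X, y).score(X, y)
    assert oracle >= 0.99
    cfg = NetworkConfig(n_layers=2, n_neurons=16, learning_rate=3e-3,
                        epochs=60, dropout_enabled=False, seed=1)
    net = build_network(cfg, X.shape[1], 2)
    _, hist = train(net, X, y, None, None, cfg)
    assert hist.epochs[-1].train_accuracy >= 0.95


def test_training_loss_matches_logistic_oracle():
    """A 1-hidden-layer net (width >= features, no dropout) is at least as
    expressive as multinomial logistic regression: its converged training
    loss is within 0.05 of the L2-regularised logistic oracle's."""
    X, y = _separable(n=80, f=6, seed=3, gap=2.0)
    clf = LogisticRegression(C=1.0, max_iter=2000).fit(X, y)
    P = clf.predict_proba(X)
    oracle_loss = -np.mean(np.log(P[np.arange(len(y)), y]))
    cfg = NetworkConfig(n_layers=1, n_neurons=12, dropout_enabled=False,
                        learning_rate=5e-3, epochs=300, batch_size=80, seed=2)
    net = build_network(cfg, X.shape[1], 2)
    _, hist = train(net, X, y, None, None, cfg)
    assert hist.epochs[-1].train_loss <= oracle_loss + 0.05


def test_best_epoch_checkpointing():
    X, y = _separable(n=80, seed=5)
    cfg = NetworkConfig(n_layers=2, n_neurons=8, learning_rate=1e-3, epochs=15,
                        dropout_enabled=False, seed=5)
    net = build_network(cfg, X.shape[1], 2)
    model, hist = train(net, X[:60], y[:60], X[60:], y[60:], cfg)
    accs = [r.validation_accuracy for r in hist.epochs]
    assert hist.best_epoch == int(np.argmax(accs))  # earliest max
    proba = predict_proba(model, X[60:])
    assert float(np.mean(proba.argmax(1) == y[60:])) == pytest.approx(max(accs))


def test_divergence_raises():
    X, y = _separable(n=20)
    X[0, 0] = np.inf  # propagates to a non-finite loss
    cfg = NetworkConfig(n_layers=3, epochs=2, seed=0, dropout_enabled=False)
    net = build_network(cfg, X.shape[1], 2)
    with pytest.raises(DivergedError, match="epoch"):
        train(net, X, y, None, None, cfg)


def test_empty_training_set_rejected():
    cfg = NetworkConfig()
    net = build_network(cfg, 3, 2)
    with pytest.raises(PhenodeepError, match="empty"):
        train(net, np.zeros((0, 3)), np.zeros(0, dtype=int), None, None, cfg)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_predict_proba_rows_sum_to_one():
    net = build_network(NetworkConfig(n_layers=2, seed=1), 4, 3)
    # give the output layer nonzero weights so rows are non-trivial
    net.weights[-1] = np.random.default_rng(0).normal(size=net.weights[-1].shape)
    model = TrainedModel(config=net.config, network=net)
    proba = predict_proba(model, np.random.default_rng(1).normal(size=(7, 4)))
    assert proba.shape == (7, 3)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
    assert proba.min() >= 0 and proba.max() <= 1


def test_untrained_network_is_uniform():
    """Zero-initialised output layer -> exactly uniform class probabilities."""
    net = build_network(NetworkConfig(n_layers=2, seed=0), 5, 4)
    model = TrainedModel(config=net.config, network=net)
    proba = predict_proba(model, np.random.default_rng(2).normal(size=(3, 5)))
    np.testing.assert_allclose(proba, 0.25)


def test_predict_duplicate_rows_identical():
    net = build_network(NetworkConfig(n_layers=1, seed=3), 4, 2)
    model = TrainedModel(config=net.config, network=net)
    x = np.array([[1.0, 2.0, 3.0, 4.0]] * 2)
    proba = predict_proba(model, x)
    np.testing.assert_array_equal(proba[0], proba[1])


def test_width_mismatch_names_sizes():
    net = build_network(NetworkConfig(n_layers=1), 4, 2)
    model = TrainedModel(config=net.config, network=net)
    with pytest.raises(PhenodeepError, match="4"):
        predict_proba(model, np.zeros((2, 7)))


def test_predict_label_tie_breaks_to_first():
    net = build_network(NetworkConfig(n_layers=1, seed=0), 3, 2)
    model = TrainedModel(config=net.config, network=net, label_order=["healthy", "sick"])
    labels = predict_label(model, np.zeros((2, 3)))  # uniform -> tie
    assert labels == ["healthy", "healthy"]


def test_predict_label_maps_encoding():
    net = build_network(NetworkConfig(n_layers=1, n_neurons=2, seed=0), 2, 2)
    net.weights[-1] = np.array([[0.0, 5.0], [0.0, 5.0]])
    model = TrainedModel(config=net.config, network=net, label_order=["healthy", "sick"])
    assert predict_label(model, np.ones((1, 2))) == ["sick"]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _trained_model(seed=0):
    X, y = _separable(n=40, seed=seed)
    cfg = NetworkConfig(n_layers=2, n_neurons=6, epochs=2, seed=seed)
    net = build_network(cfg, X.shape[1], 2)
    model, _ = train(net, X, y, None, None, cfg)
    model.label_order = ["a", "b"]
    model.retained_taxa = [f"k__B|s__T{i}" for i in range(X.shape[1])]
    return model, X


def test_save_load_bit_identical(tmp_path):
    model, X = _trained_model()
    p = tmp_path / "m.zip"
    save_model(model, p)
    loaded = load_model(p)
    np.testing.assert_array_equal(predict_proba(model, X), predict_proba(loaded, X))
    assert loaded.label_order == model.label_order
    assert loaded.retained_taxa == model.retained_taxa


def test_archive_format_version(tmp_path):
    import zipfile

    model, _ = _trained_model()
    p = tmp_path / "m.zip"
    save_model(model, p)
    with zipfile.ZipFile(p) as zf:
        assert zf.read("format_version").decode() == "1"


def test_truncated_archive_errors(tmp_path):
    model, _ = _trained_model()
    p = tmp_path / "m.zip"
    save_model(model, p)
    data = p.read_bytes()
    p.write_bytes(data[: len(data) // 2])
    with pytest.raises(ModelArchiveError):
        load_model(p)


def test_missing_file_errors(tmp_path):
    with pytest.raises(ModelArchiveError):
        load_model(tmp_path / "nope.zip")


def test_cross_entropy_matches_direct():
    logits = np.array([[2.0, -1.0], [0.5, 0.5]])
    y = np.array([0, 1])
    p = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
    direct = -np.mean(np.log(p[np.arange(2), y]))
    assert _cross_entropy(logits, y) == pytest.approx(direct, rel=1e-12)
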