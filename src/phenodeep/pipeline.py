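"""End-to-end plumbing: profile + metadata in, trained model + report out.

``train_pipeline`` runs the fixed sequence (align, rank restriction,
closure to percent, stratified split, abundance filtering on the training
partition, CSS fitted on the training partition, feature assembly,
training, test-set evaluation) and returns everything a caller might save.
``transform_features`` replays a trained model's stored preprocessing on a
new table, so predictions on unknown samples see exactly the training-time
feature space.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import PhenodeepError
from .evaluate import EvaluationReport, evaluate_predictions
from .model import (
    NetworkConfig,
    TrainedModel,
    TrainingHistory,
    build_network,
    predict_proba,
    train,
)
from .preprocess import (
    DataSplit,
    PreprocessConfig,
    assemble_features,
    css_normalize,
    filter_abundance,
    restrict_to_rank,
    stratified_split,
    to_relative_percent,
)
from .table import AbundanceTable, SampleMetadata, align_table_metadata

__all__ = ["PipelineResult", "train_pipeline", "transform_features", "predict_samples"]


@dataclass
class PipelineResult:
    model: TrainedModel
    history: TrainingHistory
    report: EvaluationReport
    split: DataSplit
    test_sample_ids: list[str] = field(default_factory=list)
    test_proba: np.ndarray | None = None
    test_true: np.ndarray | None = None


def train_pipeline(
    table: AbundanceTable,
    meta: SampleMetadata,
    preprocess_config: PreprocessConfig | None = None,
    network_config: NetworkConfig | None = None,
) -> PipelineResult:
    """Train a classifier from a raw abundance table and labels."""
    pre = preprocess_config or PreprocessConfig()
    net_cfg = network_config or NetworkConfig()
    table, meta = align_table_metadata(table, meta, "intersect")
    t = restrict_to_rank(table, pre.rank)
    t = to_relative_percent(t)
    split = stratified_split(meta, pre)
    t, retained = filter_abundance(t, pre.abundance_threshold, reference_ids=split.train_ids)
    state = None
    if pre.normalize:
        _, state = css_normalize(t.select_samples(split.train_ids), pre.css_quantile)
        t, state = css_normalize(t, state=state)
    X, y = assemble_features(t, retained, meta)
    row = {s: i for i, s in enumerate(t.sample_ids)}

    def part(ids):
        idx = [row[s] for s in ids]
        return X[idx], y[idx]

    Xtr, ytr = part(split.train_ids)
    Xv, yv = part(split.validation_ids)
    Xte, yte = part(split.test_ids)

    net = build_network(net_cfg, len(retained), meta.n_classes)
    model, history = train(net, Xtr, ytr, Xv, yv, net_cfg)
    model.retained_taxa = retained
    model.normalization = state
    model.label_order = list(meta.label_order)
    model.preprocess = asdict(pre)

    proba = predict_proba(model, Xte)
    report = evaluate_predictions(yte, proba)
    return PipelineResult(
        model=model,
        history=history,
        report=report,
        split=split,
        test_sample_ids=list(split.test_ids),
        test_proba=proba,
        test_true=yte,
    )


def transform_features(model: TrainedModel, table: AbundanceTable) -> tuple[np.ndarray, list[str]]:
    """Replay the stored preprocessing on a (possibly unlabeled) table.

    Novel taxa are ignored; retained taxa missing from the table contribute
    zero columns.  Applied to the training table this reproduces the
    training feature matrix bit-for-bit.
    """
    if not model.preprocess:
        raise PhenodeepError("model archive carries no preprocessing state")
    pre = PreprocessConfig(**model.preprocess)
    t = restrict_to_rank(table, pre.rank)
    t = to_relative_percent(t)
    X, _ = assemble_features(t, model.retained_taxa)
    projected = AbundanceTable(
        list(t.sample_ids),
        [_taxon(tid) for tid in model.retained_taxa],
        X,
        "relative_percent",
    )
    if model.normalization is not None:
        projected, _ = css_normalize(projected, state=model.normalization)
    return projected.values, list(projected.sample_ids)


def _taxon(display_id: str):
    from .taxa import TaxonEntry

    return TaxonEntry.from_display_id(display_id)


def predict_samples(
    model: TrainedModel, table: AbundanceTable
) -> tuple[list[str], np.ndarray, list[str]]:
    """Predicted labels and class probabilities for each sample of a table."""
    X, sample_ids = transform_features(model, table)
    proba = predict_proba(model, X)
    idx = proba.argmax(axis=1)
    labels = [model.label_order[i] for i in idx]
    return labels, proba, sample_ids


def _fit_fold(
    table: AbundanceTable,
    meta: SampleMetadata,
    pre: PreprocessConfig,
    net_cfg: NetworkConfig,
    train_ids: list[str],
    test_ids: list[str],
) -> float:
    """One cross-validation fold: refit preprocessing on the training ids,
    train without a validation set, return held-out accuracy."""
    t = restrict_to_rank(table, pre.rank)
    t = to_relative_percent(t)
    t, retained = filter_abundance(t, pre.abundance_threshold, reference_ids=train_ids)
    state = None
    if pre.normalize:
        _, state = css_normalize(t.select_samples(train_ids), pre.css_quantile)
        t, state = css_normalize(t, state=state)
    X, y = assemble_features(t, retained, meta)
    row = {s: i for i, s in enumerate(t.sample_ids)}
    tr = [row[s] for s in train_ids]
    te = [row[s] for s in test_ids]
    net = build_network(net_cfg, len(retained), meta.n_classes)
    model, _ = train(net, X[tr], y[tr], None, None, net_cfg)
    proba = predict_proba(model, X[te])
    return float(np.mean(proba.argmax(axis=1) == y[te]))
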