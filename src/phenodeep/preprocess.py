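"""Feature preparation: rank restriction, closure, filtering, CSS, splitting.

The pipeline order is fixed: restrict to one taxonomic rank, convert to
relative percent, drop low-abundance taxa, cumulative-sum-scaling
normalisation (optional), then stratified splitting / feature assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import PreprocessError, SplitError
from .table import AbundanceTable, SampleMetadata
from .taxa import RANKS

__all__ = [
    "PreprocessConfig",
    "NormalizationState",
    "DataSplit",
    "restrict_to_rank",
    "to_relative_percent",
    "filter_abundance",
    "css_normalize",
    "stratified_split",
    "assemble_features",
]


@dataclass
class PreprocessConfig:
    """Preprocessing hyperparameters.

    ``abundance_threshold`` is on the percent scale: the default 0.03 keeps
    taxa whose maximum relative abundance reaches 0.03 % in at least one
    reference sample.  ``validation_fraction`` applies to the non-test
    remainder.
    """

    rank: str = "species"
    abundance_threshold: float = 0.03
    normalize: bool = True
    css_quantile: float = 0.5
    test_fraction: float = 0.15
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise PreprocessError(f"unknown rank {self.rank!r}")
        if self.abundance_threshold < 0:
            raise PreprocessError("abundance_threshold must be >= 0")
        if not 0 < self.css_quantile < 1:
            raise PreprocessError("css_quantile must be in (0, 1)")
        if not 0 < self.test_fraction < 1:
            raise PreprocessError("test_fraction must be in (0, 1)")
        if not 0 <= self.validation_fraction < 1:
            raise PreprocessError("validation_fraction must be in [0, 1)")
        remainder = (1 - self.test_fraction) * self.validation_fraction
        if self.test_fraction + remainder >= 1:
            raise PreprocessError("train partition would be empty")


@dataclass
class NormalizationState:
    """Fitted CSS state: the quantile, the reference scale (median of the
    training samples' cumulative factors) and the per-sample factors."""

    css_quantile: float
    reference_scale: float
    per_sample_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_scale <= 0:
            raise PreprocessError("reference_scale must be positive")
        for sid, f in self.per_sample_factors.items():
            if f <= 0:
                raise PreprocessError(f"non-positive CSS factor for sample {sid!r}")


@dataclass
class DataSplit:
    train_ids: list[str]
    validation_ids: list[str]
    test_ids: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [self.train_ids, self.validation_ids, self.test_ids]
        all_ids = [s for p in parts for s in p]
        if len(set(all_ids)) != len(all_ids):
            raise SplitError("split partitions overlap")


def restrict_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Keep only taxa whose terminal rank equals ``rank`` (order preserved)."""
    if rank not in RANKS:
        raise PreprocessError(f"unknown rank {rank!r}")
    keep = [i for i, t in enumerate(table.taxa) if t.rank == rank]
    if not keep:
        raise PreprocessError(f"no taxa at rank {rank!r}")
    return table.select_taxa(keep)


def to_relative_percent(table: AbundanceTable) -> AbundanceTable:
    """Close each sample to 100 %.  Percent input is returned unchanged."""
    if table.value_kind == "relative_percent":
        return table
    totals = table.values.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise PreprocessError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total abundance"
        )
    values = table.values / totals[:, None] * 100.0
    return AbundanceTable(list(table.sample_ids), list(table.taxa), values, "relative_percent")


def filter_abundance(
    table: AbundanceTable,
    threshold: float,
    reference_ids: list[str] | None = None,
) -> tuple[AbundanceTable, list[str]]:
    """Drop taxa whose maximum relative abundance over the reference samples
    is below ``threshold`` (percent scale, boundary inclusive).

    Returns the filtered table and the retained taxon display ids, which are
    what a trained model stores and later re-applies to unknown samples.
    """
    if threshold < 0:
        raise PreprocessError("threshold must be >= 0")
    if table.value_kind != "relative_percent":
        raise PreprocessError("filter_abundance expects a relative_percent table")
    ref = table if reference_ids is None else table.select_samples(reference_ids)
    maxima = ref.values.max(axis=0) if ref.n_samples else np.zeros(table.n_taxa)
    keep = [j for j in range(table.n_taxa) if maxima[j] >= threshold]
    if not keep:
        raise PreprocessError(
            f"no taxon passes abundance threshold {threshold} "
            f"(max observed {maxima.max() if maxima.size else 0.0:.6g})"
        )
    filtered = table.select_taxa(keep)
    return filtered, filtered.taxon_ids


def css_factor(values: np.ndarray, quantile: float) -> float:
    """CSS factor of one sample: the sum of its values that are <= the
    ``quantile``-th quantile (linear interpolation) of its positive values."""
    pos = values[values > 0]
    if pos.size == 0:
        raise PreprocessError("sample has no positive values")
    qv = float(np.quantile(pos, quantile))
    return float(values[values <= qv].sum())


def css_normalize(
    table: AbundanceTable,
    quantile: float = 0.5,
    state: NormalizationState | None = None,
) -> tuple[AbundanceTable, NormalizationState]:
    """Cumulative sum scaling.

    Fitting (``state is None``): each sample j gets factor ``s_j`` from
    :func:`css_factor`; the reference scale is the median factor; values are
    mapped to ``v / s_j * reference_scale``.  Applying (``state`` given): the
    stored reference scale is reused and factors are computed fresh for the
    new samples, so normalisation of one sample never depends on which other
    samples accompany it.
    """
    if state is None:
        if not 0 < quantile < 1:
            raise PreprocessError("quantile must be in (0, 1)")
        q = quantile
        ref = None
    else:
        q = state.css_quantile
        ref = state.reference_scale
    factors: dict[str, float] = {}
    for i, sid in enumerate(table.sample_ids):
        try:
            factors[sid] = css_factor(table.values[i], q)
        except PreprocessError as exc:
            raise PreprocessError(f"sample {sid!r}: {exc}") from exc
    if ref is None:
        ref = float(np.median(list(factors.values())))
    values = table.values.copy()
    for i, sid in enumerate(table.sample_ids):
        values[i] = table.values[i] / factors[sid] * ref
    out_state = NormalizationState(q, ref, factors)
    out = AbundanceTable(list(table.sample_ids), list(table.taxa), values, table.value_kind)
    return out, out_state


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(meta: SampleMetadata, config: PreprocessConfig) -> DataSplit:
    """Deterministic stratified train/validation/test split.

    Per class: shuffle with a generator seeded from ``config.seed``, give the
    test partition ``round(test_fraction * n_c)`` samples (at least one),
    then the validation partition likewise from the remainder.
    """
    rng = np.random.default_rng(config.seed)
    by_class: dict[str, list[str]] = {lab: [] for lab in meta.label_order}
    for sid, lab in meta.mapping.items():
        by_class[lab].append(sid)
    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    need = 3 if config.validation_fraction > 0 else 2
    for lab in meta.label_order:
        ids = by_class[lab]
        if len(ids) < need:
            raise SplitError(
                f"class {lab!r} has {len(ids)} samples; needs >= {need} "
                "(one per partition)"
            )
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n_test = max(1, _round_half_away(config.test_fraction * len(ids)))
        test.extend(ids[:n_test])
        rest = ids[n_test:]
        if config.validation_fraction > 0:
            n_val = max(1, _round_half_away(config.validation_fraction * len(rest)))
        else:
            n_val = 0
        val.extend(rest[:n_val])
        train.extend(rest[n_val:])
        if not rest[n_val:]:
            raise SplitError(f"class {lab!r}: no samples left for training")
    return DataSplit(train, val, test, config.seed)


def assemble_features(
    table: AbundanceTable,
    retained_taxa: list[str],
    meta: SampleMetadata | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Project a table onto the retained taxon list.

    Columns follow ``retained_taxa`` order; taxa absent from the table are
    filled with zeros (an unknown sample simply lacks them).  When ``meta``
    is given, the encoded integer label vector is returned alongside.
    """
    col = {t.display_id: j for j, t in enumerate(table.taxa)}
    X = np.zeros((table.n_samples, len(retained_taxa)))
    for k, tid in enumerate(retained_taxa):
        j = col.get(tid)
        if j is not None:
            X[:, k] = table.values[:, j]
    y = meta.encoded(table.sample_ids) if meta is not None else None
    return X, y
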