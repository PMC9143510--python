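"""In-memory containers: abundance tables and sample metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, MetadataError, PhenodeepError
from .taxa import TaxonEntry

#: How the cell values of a table are to be read.
VALUE_KINDS = ("counts", "relative_percent", "relative_fraction")


@dataclass
class AbundanceTable:
    """A dense samples x taxa abundance matrix.

    ``values[i, j]`` is the abundance of taxon ``j`` in sample ``i``; the
    interpretation (read counts vs. relative abundance) is carried by
    ``value_kind``.  Rows are samples, matching the feature-vector-per-sample
    view the classifier consumes.
    """

    sample_ids: list[str]
    taxa: list[TaxonEntry]
    values: np.ndarray
    value_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxa)):
            raise PhenodeepError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxa)} taxa"
            )
        if self.value_kind not in VALUE_KINDS:
            raise PhenodeepError(f"unknown value_kind {self.value_kind!r}")
        if self.values.size and np.nanmin(self.values) < 0:
            raise PhenodeepError("abundance values must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise PhenodeepError(f"duplicate sample id {dup!r}")
        ids = [t.display_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            dup = _first_duplicate(ids)
            raise PhenodeepError(f"duplicate taxon {dup!r}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def taxon_ids(self) -> list[str]:
        return [t.display_id for t in self.taxa]

    # -- subsetting ------------------------------------------------------
    def select_samples(self, ids: list[str]) -> "AbundanceTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in ids]
        return AbundanceTable(list(ids), list(self.taxa), self.values[rows], self.value_kind)

    def select_taxa(self, indices: list[int]) -> "AbundanceTable":
        taxa = [self.taxa[i] for i in indices]
        return AbundanceTable(list(self.sample_ids), taxa, self.values[:, indices], self.value_kind)

    def sorted_by_taxon(self) -> "AbundanceTable":
        """Canonical ordering: lexicographic by display_id."""
        order = sorted(range(self.n_taxa), key=lambda i: self.taxa[i].display_id)
        return self.select_taxa(order)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


def _first_duplicate(items) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""  # pragma: no cover


@dataclass
class SampleMetadata:
    """Sample id -> class label mapping with a fixed label encoding.

    ``label_order`` is the lexicographically sorted list of distinct labels
    and ``label_index`` maps each label to its integer code ``0..N-1``.  The
    encoding is frozen at construction so that subsets taken later (e.g. a
    train partition) keep the original code assignment.
    """

    mapping: dict[str, str]
    label_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label_order:
            self.label_order = sorted(set(self.mapping.values()))
            if len(self.label_order) < 2:
                raise MetadataError(
                    f"need >=2 classes, found {len(self.label_order)}: {self.label_order}"
                )
        unknown = sorted(set(self.mapping.values()) - set(self.label_order))
        if unknown:
            raise MetadataError(f"labels missing from label_order: {unknown}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mapping)

    @property
    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.label_order)}

    @property
    def n_classes(self) -> int:
        return len(self.label_order)

    def encoded(self, sample_ids: list[str]) -> np.ndarray:
        """Integer label vector for the given samples, in the given order."""
        idx = self.label_index
        try:
            return np.array([idx[self.mapping[s]] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - guarded upstream
            raise AlignmentError(f"sample without label: {exc.args[0]!r}") from exc

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise AlignmentError(f"samples without metadata: {missing}")
        return SampleMetadata(
            {s: self.mapping[s] for s in sample_ids}, list(self.label_order)
        )


def align_table_metadata(
    table: AbundanceTable,
    meta: SampleMetadata,
    policy: str = "intersect",
) -> tuple[AbundanceTable, SampleMetadata]:
    """Restrict table and metadata to a common sample set.

    ``intersect`` keeps the shared ids in table order; ``strict`` demands the
    two id sets match exactly and errors otherwise, listing the offenders.
    """
    table_ids = set(table.sample_ids)
    meta_ids = set(meta.mapping)
    shared = [s for s in table.sample_ids if s in meta_ids]
    if policy == "strict":
        only_table = sorted(table_ids - meta_ids)
        only_meta = sorted(meta_ids - table_ids)
        if only_table or only_meta:
            raise AlignmentError(
                "sample sets differ; "
                f"only in table: {only_table}; only in metadata: {only_meta}"
            )
        return table, meta.subset(table.sample_ids)
    if policy != "intersect":
        raise ValueError(f"unknown alignment policy {policy!r}")
    if not shared:
        raise AlignmentError("no shared sample ids between table and metadata")
    return table.select_samples(shared), meta.subset(shared)
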