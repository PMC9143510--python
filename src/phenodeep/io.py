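"""Readers and writers for taxonomic abundance profiles and metadata.

Three profile dialects are supported:

* generic OTU table — TSV, one row per taxon (pipe-joined lineage string),
  one column per sample;
* Kraken2-style per-sample report files (6 tab-separated columns);
* MetaPhlAn-style merged relative-abundance tables.

All readers return an :class:`~phenodeep.table.AbundanceTable`.
"""

from __future__ import annotations

import os

import numpy as np

from .errors import MetadataError, PhenodeepError, ProfileParseError
from .table import AbundanceTable, SampleMetadata
from .taxa import RANK_INDEX, TaxonEntry

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_kraken_reports",
    "read_metaphlan_table",
    "write_metaphlan_table",
    "read_metadata",
    "write_metadata",
]


# ---------------------------------------------------------------------------
# generic OTU table
# ---------------------------------------------------------------------------

def read_otu_table(path: str | os.PathLike, value_kind: str | None = None) -> AbundanceTable:
    """Read a generic TSV OTU table (taxa rows x sample columns).

    ``value_kind`` is inferred when not forced: if every sample's
    species-rank values sum to within [99, 101] the table is treated as
    ``relative_percent``, otherwise as ``counts``.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ProfileParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ProfileParseError(f"{path}: header has no sample columns")
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise ProfileParseError(f"{path}: duplicate sample column {s!r}")
        seen.add(s)

    taxa: list[TaxonEntry] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ProfileParseError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        try:
            taxon = TaxonEntry.from_display_id(fields[0])
        except PhenodeepError as exc:
            raise ProfileParseError(f"{path}:{lineno}: {exc}") from exc
        vals = []
        for cell in fields[1:]:
            try:
                v = float(cell)
            except ValueError as exc:
                raise ProfileParseError(
                    f"{path}:{lineno}: non-numeric abundance {cell!r}"
                ) from exc
            if v < 0:
                raise ProfileParseError(f"{path}:{lineno}: negative abundance {v}")
            vals.append(v)
        taxa.append(taxon)
        rows.append(vals)
    if not taxa:
        raise ProfileParseError(f"{path}: no taxon rows")
    values = np.array(rows, dtype=float).T  # samples x taxa
    if value_kind is None:
        value_kind = _infer_value_kind(taxa, values)
    return AbundanceTable(list(sample_ids), taxa, values, value_kind)


def _infer_value_kind(taxa: list[TaxonEntry], values: np.ndarray) -> str:
    species = [i for i, t in enumerate(taxa) if t.rank == "species"]
    if species:
        sums = values[:, species].sum(axis=1)
        if np.all((sums >= 99.0) & (sums <= 101.0)):
            return "relative_percent"
    return "counts"


def write_otu_table(table: AbundanceTable, path: str | os.PathLike) -> None:
    """Write the generic TSV dialect; :func:`read_otu_table` inverts it."""
    if table.n_taxa == 0:
        raise PhenodeepError("empty table: no taxa to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon\t" + "\t".join(table.sample_ids) + "\n")
        for j, taxon in enumerate(table.taxa):
            cells = "\t".join(repr(float(v)) for v in table.values[:, j])
            fh.write(f"{taxon.display_id}\t{cells}\n")


# ---------------------------------------------------------------------------
# Kraken2-style reports
# ---------------------------------------------------------------------------

# canonical single-letter rank codes; anything else (R, U, S1, G2, ...) is
# treated as an unranked / below-rank node and never becomes a feature.
_KRAKEN_RANK = {
    "D": "kingdom",  # Kraken2 prints domains at the top level
    "K": "kingdom",
    "P": "phylum",
    "C": "class",
    "O": "order",
    "F": "family",
    "G": "genus",
    "S": "species",
}


def read_kraken_reports(
    paths: list[tuple[str, str | os.PathLike]],
    column: str = "clade_count",
) -> AbundanceTable:
    """Merge per-sample Kraken2 report files into one table.

    ``paths`` is a list of ``(sample_id, file_path)`` pairs.  ``column``
    selects which report column becomes the table value: ``clade_count``
    (reads covering the clade; the default, giving ``value_kind='counts'``)
    or ``percent``.

    Lineages are reconstructed from the report's 2-space indentation.  Rows
    whose rank code is not one of D/K/P/C/O/F/G/S (root, unclassified, or
    suffixed sub-ranks such as ``S1``) stay on the indentation stack but do
    not become features.  Taxa absent from a sample get value 0, and the
    merged taxon order is lexicographic by display id.
    """
    if column not in ("clade_count", "percent"):
        raise ValueError(f"unknown kraken column {column!r}")
    per_sample: list[dict[str, float]] = []
    registry: dict[str, TaxonEntry] = {}
    sample_ids: list[str] = []
    for sample_id, path in paths:
        sample_ids.append(sample_id)
        counts = _read_one_kraken(path, column, registry)
        per_sample.append(counts)
    if len(set(sample_ids)) != len(sample_ids):
        raise ProfileParseError("duplicate sample ids among kraken reports")
    taxon_ids = sorted(registry)
    taxa = [registry[t] for t in taxon_ids]
    values = np.zeros((len(sample_ids), len(taxa)))
    col = {t: j for j, t in enumerate(taxon_ids)}
    for i, counts in enumerate(per_sample):
        for tid, v in counts.items():
            values[i, col[tid]] = v
    kind = "counts" if column == "clade_count" else "relative_percent"
    return AbundanceTable(sample_ids, taxa, values, kind)


def _read_one_kraken(
    path: str | os.PathLike, column: str, registry: dict[str, TaxonEntry]
) -> dict[str, float]:
    counts: dict[str, float] = {}
    # stack of (depth, rank-or-None, name) for lineage reconstruction
    stack: list[tuple[int, str | None, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ProfileParseError(
                    f"{path}:{lineno}: expected 6 tab-separated columns"
                )
            pct_s, clade_s, _direct_s, code, _taxid, raw_name = fields[:6]
            try:
                pct = float(pct_s)
                clade = float(clade_s)
            except ValueError as exc:
                raise ProfileParseError(
                    f"{path}:{lineno}: non-numeric count field"
                ) from exc
            depth = (len(raw_name) - len(raw_name.lstrip(" "))) // 2
            name = raw_name.strip()
            while stack and stack[-1][0] >= depth:
                stack.pop()
            rank = _KRAKEN_RANK.get(code)
            if rank is not None:
                lineage = [
                    (r, n) for _, r, n in stack if r is not None
                ] + [(rank, name)]
                # drop nodes that would break strict rank descent (e.g. a K
                # line nested under a D line maps to the same rank)
                cleaned: list[tuple[str, str]] = []
                for r, n in lineage:
                    if not cleaned or RANK_INDEX[r] > RANK_INDEX[cleaned[-1][0]]:
                        cleaned.append((r, n))
                if cleaned[-1][1] == name:
                    taxon = TaxonEntry(tuple(cleaned))
                    registry.setdefault(taxon.display_id, taxon)
                    value = clade if column == "clade_count" else pct
                    counts[taxon.display_id] = counts.get(taxon.display_id, 0.0) + value
                    stack.append((depth, rank, name))
                    continue
            stack.append((depth, None, name))
    if not counts:
        raise ProfileParseError(f"{path}: no classified taxa")
    return counts


# ---------------------------------------------------------------------------
# MetaPhlAn-style merged table
# ---------------------------------------------------------------------------

def read_metaphlan_table(path: str | os.PathLike) -> AbundanceTable:
    """Read a merged MetaPhlAn-style relative-abundance table (percent scale).

    The first non-comment line is the header (clade column + sample names);
    each body row's first field is a ``k__...|s__...`` clade string whose
    deepest prefix sets the taxon's rank.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    lines = [ln for ln in lines if not ln.startswith("#")]
    if not lines:
        raise ProfileParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ProfileParseError(f"{path}: header has no sample columns")
    taxa: list[TaxonEntry] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ProfileParseError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        try:
            taxon = TaxonEntry.from_display_id(fields[0])
        except PhenodeepError as exc:
            raise ProfileParseError(f"{path}:{lineno}: {exc}") from exc
        try:
            vals = [float(c) for c in fields[1:]]
        except ValueError as exc:
            raise ProfileParseError(f"{path}:{lineno}: non-numeric abundance") from exc
        taxa.append(taxon)
        rows.append(vals)
    if not taxa:
        raise ProfileParseError(f"{path}: no clade rows")
    values = np.array(rows, dtype=float).T
    return AbundanceTable(list(sample_ids), taxa, values, "relative_percent")


def write_metaphlan_table(table: AbundanceTable, path: str | os.PathLike) -> None:
    """Write a MetaPhlAn-style merged table (values must be percent scale)."""
    if table.value_kind != "relative_percent":
        raise PhenodeepError("metaphlan tables hold relative percent values")
    if table.n_taxa == 0:
        raise PhenodeepError("empty table: no taxa to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("clade_name\t" + "\t".join(table.sample_ids) + "\n")
        for j, taxon in enumerate(table.taxa):
            cells = "\t".join(repr(float(v)) for v in table.values[:, j])
            fh.write(f"{taxon.display_id}\t{cells}\n")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

_HEADER_TOKENS = {"sample_id", "sampleid", "sample", "#sample_id", "id"}


def read_metadata(path: str | os.PathLike) -> SampleMetadata:
    """Read a two-column (sample id, class label) TSV, optional header."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise MetadataError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, label = fields[0].strip(), fields[1].strip()
            if lineno == 1 and sid.lower() in _HEADER_TOKENS:
                continue
            if sid in mapping and mapping[sid] != label:
                raise MetadataError(
                    f"{path}:{lineno}: conflicting labels for sample {sid!r}: "
                    f"{mapping[sid]!r} vs {label!r}"
                )
            mapping[sid] = label
    if not mapping:
        raise MetadataError(f"{path}: no samples")
    return SampleMetadata(mapping)


def write_metadata(meta: SampleMetadata, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, label in meta.mapping.items():
            fh.write(f"{sid}\t{label}\n")
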