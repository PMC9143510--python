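"""Taxonomic identities of abundance-table features.

A feature (OTU / clade) is identified by its lineage: an ordered list of
(rank, name) pairs from kingdom down to its terminal rank.  The canonical
string form is the pipe-joined, rank-prefixed convention used by MetaPhlAn
merged tables, e.g. ``k__Bacteria|p__Firmicutes|...|s__Faecalibacterium_prausnitzii``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

from .errors import LineageParseError

#: Recognised ranks, shallowest first.
RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}

#: Single-letter prefix used in the pipe-joined string form.
RANK_PREFIX: dict[str, str] = {
    "kingdom": "k",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
}
PREFIX_RANK: dict[str, str] = {v: k for k, v in RANK_PREFIX.items()}


@dataclass(frozen=True)
class TaxonEntry:
    """One taxon with its full lineage.

    Parameters
    ----------
    lineage
        Ordered ``(rank, name)`` pairs, shallowest first.  Ranks must be
        drawn from :data:`RANKS`, strictly descending, without duplicates.
    """

    lineage: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.lineage:
            raise LineageParseError("empty lineage")
        last = -1
        for rank, name in self.lineage:
            if rank not in RANK_INDEX:
                raise LineageParseError(f"unknown rank {rank!r}")
            if RANK_INDEX[rank] <= last:
                raise LineageParseError(
                    f"lineage ranks must strictly descend; {rank!r} out of order "
                    f"in {self.lineage!r}"
                )
            if not name:
                raise LineageParseError("empty taxon name in lineage")
            last = RANK_INDEX[rank]

    @property
    def rank(self) -> str:
        """Terminal (deepest) rank of this entry."""
        return self.lineage[-1][0]

    @property
    def name(self) -> str:
        """Name at the terminal rank."""
        return self.lineage[-1][1]

    @cached_property
    def display_id(self) -> str:
        """Canonical pipe-joined, rank-prefixed identifier."""
        return "|".join(f"{RANK_PREFIX[r]}__{n}" for r, n in self.lineage)

    @classmethod
    def from_display_id(cls, text: str) -> "TaxonEntry":
        """Parse a pipe-joined identifier back into a :class:`TaxonEntry`.

        Raises
        ------
        LineageParseError
            If any segment lacks the ``<letter>__`` prefix or uses an
            unknown prefix letter.
        """
        pairs = []
        for segment in text.split("|"):
            if "__" not in segment:
                raise LineageParseError(
                    f"segment {segment!r} lacks a rank prefix (expected like 'k__Name')"
                )
            prefix, name = segment.split("__", 1)
            if prefix not in PREFIX_RANK:
                raise LineageParseError(
                    f"unknown rank prefix {prefix + '__'!r} in {text!r}"
                )
            pairs.append((PREFIX_RANK[prefix], name))
        return cls(tuple(pairs))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display_id
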