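"""Synthetic case/control abundance tables with controllable class signal.

The generator emulates the statistical character of real taxonomic
profiles — heavy-tailed (log-normal) abundances, compositional closure,
zero inflation — without any community ecology: taxa are independent, and
the class effect is a multiplicative shift of a fixed set of informative
taxa.  It exists so the whole pipeline can be exercised and benchmarked
without downloading real datasets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import PhenodeepError
from .table import AbundanceTable, SampleMetadata
from .taxa import TaxonEntry

__all__ = ["SynthConfig", "generate", "generate_kraken_reports"]


@dataclass
class SynthConfig:
    """Study conditions for a simulated case/control cohort.

    Defaults describe the benchmark cohort used throughout the test suite:
    two balanced classes of 100 samples, 200 species of which 20 are
    informative with a log-fold-change of 3 (about 20x) in cases, moderate
    zero inflation, and a sequencing depth of 100k reads per sample.
    """

    n_per_class: list[int] = field(default_factory=lambda: [100, 100])
    n_taxa: int = 200
    n_informative: int = 20
    log_fold_change: float = 3.0
    base_lognormal_mu: float = 0.0
    base_lognormal_sigma: float = 1.0
    sparsity: float = 0.3
    depth: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) < 2:
            raise PhenodeepError("need >=2 classes")
        if any(n < 1 for n in self.n_per_class):
            raise PhenodeepError("each class needs >=1 sample")
        if self.n_informative > self.n_taxa:
            raise PhenodeepError("n_informative must be <= n_taxa")
        if self.log_fold_change < 0:
            raise PhenodeepError("log_fold_change must be >= 0")
        if not 0 <= self.sparsity < 1:
            raise PhenodeepError("sparsity must be in [0, 1)")
        if self.depth < 1:
            raise PhenodeepError("depth must be >= 1")


def _lineage(i: int, genus: int) -> TaxonEntry:
    return TaxonEntry(
        (
            ("kingdom", "SynBacteria"),
            ("phylum", "SynPhylum"),
            ("class", "SynClass"),
            ("order", "SynOrder"),
            ("family", f"SynFamily_{genus:03d}"),
            ("genus", f"SynGenus_{genus:03d}"),
            ("species", f"SynSpecies_{i:04d}"),
        )
    )


def generate(config: SynthConfig) -> tuple[AbundanceTable, SampleMetadata, list[str]]:
    """Draw one labeled cohort.

    Per sample: latent per-taxon abundances are log-normal; informative
    taxa are multiplied by ``exp(log_fold_change)`` in every case class
    (all classes except ``class_0``); zeros are injected at the sparsity
    rate; the composition is closed and scaled to integer read counts.
    Taxa never observed in any sample are dropped from the emitted table.

    Returns the counts table, the metadata, and the informative taxa's
    display ids (ground truth for feature-recovery checks).
    """
    rng = np.random.default_rng(config.seed)
    taxa = [_lineage(i, i // 10) for i in range(config.n_taxa)]
    effect = np.exp(config.log_fold_change)
    rows = []
    sample_ids = []
    mapping = {}
    sample_no = 0
    for cls, n in enumerate(config.n_per_class):
        for _ in range(n):
            latent = rng.lognormal(
                config.base_lognormal_mu, config.base_lognormal_sigma, config.n_taxa
            )
            if cls > 0:
                latent[: config.n_informative] *= effect
            latent[rng.random(config.n_taxa) < config.sparsity] = 0.0
            if latent.sum() == 0:
                latent[int(rng.integers(config.n_taxa))] = 1.0
            counts = np.round(latent / latent.sum() * config.depth)
            if counts.sum() == 0:
                counts[int(np.argmax(latent))] = 1.0
            sid = f"sample_{sample_no:04d}"
            sample_no += 1
            sample_ids.append(sid)
            mapping[sid] = f"class_{cls}"
            rows.append(counts)
    values = np.array(rows)
    observed = np.flatnonzero(values.sum(axis=0) > 0)
    taxa = [taxa[j] for j in observed]
    values = values[:, observed]
    informative = [
        t.display_id for t in taxa if int(t.name.split("_")[1]) < config.n_informative
    ]
    table = AbundanceTable(sample_ids, taxa, values, "counts")
    meta = SampleMetadata(mapping)
    return table, meta, informative


def generate_kraken_reports(
    table: AbundanceTable, out_dir: str | os.PathLike
) -> list[tuple[str, str]]:
    """Render a counts table as per-sample Kraken2-style report files.

    Clade counts are summed up the lineage so every internal line equals
    the sum of its children; reading the reports back reproduces the
    species-level counts exactly.  Returns ``(sample_id, path)`` pairs.
    """
    if table.value_kind != "counts":
        raise PhenodeepError("kraken reports need a counts table")
    os.makedirs(out_dir, exist_ok=True)
    code_of = {
        "kingdom": "D",
        "phylum": "P",
        "class": "C",
        "order": "O",
        "family": "F",
        "genus": "G",
        "species": "S",
    }
    out = []
    for i, sid in enumerate(table.sample_ids):
        # aggregate clade counts keyed by lineage prefix
        clades: dict[tuple, float] = {}
        direct: dict[tuple, float] = {}
        for j, taxon in enumerate(table.taxa):
            v = float(table.values[i, j])
            if v == 0:
                continue
            for d in range(1, len(taxon.lineage) + 1):
                key = taxon.lineage[:d]
                clades[key] = clades.get(key, 0.0) + v
            direct[taxon.lineage] = direct.get(taxon.lineage, 0.0) + v
        total = sum(v for k, v in clades.items() if len(k) == 1)
        path = os.path.join(out_dir, f"{sid}.kreport")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("0.00\t0\t0\tU\t0\tunclassified\n")
            fh.write(f"100.00\t{int(total)}\t0\tR\t1\troot\n")
            taxid = 2
            for key in sorted(clades, key=lambda k: [n for _, n in k]):
                depth = len(key)  # root is depth 0
                rank, name = key[-1]
                clade = clades[key]
                dct = direct.get(key, 0.0) if rank == "species" else 0.0
                pct = clade / total * 100 if total else 0.0
                fh.write(
                    f"{pct:.2f}\t{int(clade)}\t{int(dct)}\t{code_of[rank]}\t{taxid}\t"
                    f"{'  ' * depth}{name}\n"
                )
                taxid += 1
        out.append((sid, path))
    return out
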