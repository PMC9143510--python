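import numpy as np
import pytest

from phenodeep import AbundanceTable, SampleMetadata, SynthConfig, TaxonEntry, generate


def species(i: int, genus: int = 0) -> TaxonEntry:
    return TaxonEntry(
        (
            ("kingdom", "Bacteria"),
            ("phylum", "P"),
            ("class", "C"),
            ("order", "O"),
            ("family", f"F{genus}"),
            ("genus", f"G{genus}"),
            ("species", f"S{i}"),
        )
    )


def make_table(values, value_kind="counts", sample_ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    ids = sample_ids or [f"s{i}" for i in range(n)]
    return AbundanceTable(ids, [species(j) for j in range(m)], values, value_kind)


@pytest.fixture
def small_cohort():
    """Balanced 2-class cohort with a strong class effect, small enough for
    fast pipeline tests."""
    cfg = SynthConfig(n_per_class=[20, 20], n_taxa=40, n_informative=5, seed=7)
    return generate(cfg)


@pytest.fixture
def meta_binary():
    mapping = {f"s{i}": ("sick" if i % 2 else "healthy") for i in range(10)}
    return SampleMetadata(mapping)
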