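import numpy as np
import pytest

from phenodeep import (
    NormalizationState,
    PreprocessConfig,
    PreprocessError,
    SampleMetadata,
    SplitError,
    assemble_features,
    css_normalize,
    filter_abundance,
    restrict_to_rank,
    stratified_split,
    to_relative_percent,
)
from phenodeep.taxa import TaxonEntry

from conftest import make_table


# ---------------------------------------------------------------------------
# rank restriction and closure
# ---------------------------------------------------------------------------

def test_restrict_to_rank_keeps_only_terminal_rank():
    t = make_table(np.ones((2, 2)))
    genus = TaxonEntry((("kingdom", "B"), ("genus", "G9")))
    t.taxa = t.taxa[:2] + [genus]
    t.values = np.ones((2, 3))
    sp = restrict_to_rank(t, "species")
    assert sp.n_taxa == 2
    assert all(x.rank == "species" for x in sp.taxa)
    again = restrict_to_rank(sp, "species")
    assert again.taxon_ids == sp.taxon_ids  # idempotent


def test_restrict_to_missing_rank_errors():
    t = make_table(np.ones((1, 3)))
    with pytest.raises(PreprocessError, match="genus"):
        restrict_to_rank(t, "genus")


def test_to_relative_percent_closure():
    t = make_table([[2.0, 3.0, 5.0]])
    out = to_relative_percent(t)
    np.testing.assert_allclose(out.values[0], [20, 30, 50])
    assert out.value_kind == "relative_percent"


def test_to_relative_percent_identity_on_percent():
    t = make_table([[20.0, 80.0]], value_kind="relative_percent")
    assert to_relative_percent(t) is t


def test_to_relative_percent_zero_sample_errors():
    t = make_table([[0.0, 0.0], [1.0, 1.0]])
    with pytest.raises(PreprocessError, match="s0"):
        to_relative_percent(t)


# ---------------------------------------------------------------------------
# abundance filtering
# ---------------------------------------------------------------------------

def test_filter_boundary_inclusive():
    t = make_table([[0.50, 0.02, 0.03], [0.10, 0.01, 0.02]], value_kind="relative_percent")
    out, retained = filter_abundance(t, 0.03)
    assert retained == [t.taxon_ids[0], t.taxon_ids[2]]
    assert out.n_taxa == 2


def test_filter_threshold_zero_keeps_all():
    t = make_table(np.random.default_rng(1).uniform(0, 1, (3, 5)), value_kind="relative_percent")
    _, retained = filter_abundance(t, 0.0)
    assert retained == t.taxon_ids


def test_filter_matches_brute_force_oracle():
    """Threshold filtering agrees with an exhaustive per-taxon scan for many
    random thresholds on a 200-taxon table."""
    rng = np.random.default_rng(42)
    vals = rng.uniform(0, 2, (25, 200))
    t = make_table(vals, value_kind="relative_percent")
    maxima = vals.max(axis=0)
    for thr in rng.uniform(0, 2, 20):
        expected = [t.taxon_ids[j] for j in range(200) if maxima[j] >= thr]
        _, retained = filter_abundance(t, float(thr))
        assert retained == expected


def test_filter_respects_reference_subset():
    t = make_table([[1.0, 0.0], [0.0, 1.0]], value_kind="relative_percent")
    _, retained = filter_abundance(t, 0.5, reference_ids=["s0"])
    assert retained == [t.taxon_ids[0]]


def test_filter_nothing_survives():
    t = make_table([[0.01, 0.02]], value_kind="relative_percent")
    with pytest.raises(PreprocessError, match="0.02"):
        filter_abundance(t, 5.0)


def test_filter_invariant_to_sample_order():
    rng = np.random.default_rng(3)
    t = make_table(rng.uniform(0, 1, (6, 30)), value_kind="relative_percent")
    shuffled = t.select_samples([t.sample_ids[i] for i in rng.permutation(6)])
    _, a = filter_abundance(t, 0.4)
    _, b = filter_abundance(shuffled, 0.4)
    assert a == b


# ---------------------------------------------------------------------------
# cumulative sum scaling
# ---------------------------------------------------------------------------

def test_css_hand_computed_factor():
    """Values [1,2,3,4] at q=0.5: median positive is 2.5, so s = 1+2 = 3;
    with reference equal to the sample's own factor the row is unchanged."""
    t = make_table([[1.0, 2.0, 3.0, 4.0]], value_kind="relative_percent")
    out, state = css_normalize(t, 0.5)
    assert state.per_sample_factors["s0"] == 3.0
    assert state.reference_scale == 3.0
    np.testing.assert_allclose(out.values[0], [1, 2, 3, 4])


def test_css_scale_invariance():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0.1, 5, (3, 8))
    t = make_table(vals, value_kind="relative_percent")
    _, state = css_normalize(t, 0.5)
    scaled = vals.copy()
    scaled[1] *= 10
    t2 = make_table(scaled, value_kind="relative_percent")
    out1, _ = css_normalize(t, state=state)
    out2, _ = css_normalize(t2, state=state)
    np.testing.assert_allclose(out1.values[1], out2.values[1], rtol=1e-12)


def test_css_identical_samples_identical_output():
    row = [0.5, 1.5, 3.0, 0.0]
    t = make_table([row, row], value_kind="relative_percent")
    out, state = css_normalize(t, 0.5)
    assert state.per_sample_factors["s0"] == state.per_sample_factors["s1"]
    np.testing.assert_array_equal(out.values[0], out.values[1])


def test_css_all_zero_sample_errors():
    t = make_table([[0.0, 0.0], [1.0, 2.0]], value_kind="relative_percent")
    with pytest.raises(PreprocessError, match="s0"):
        css_normalize(t, 0.5)


def test_css_bad_quantile():
    t = make_table([[1.0, 2.0]], value_kind="relative_percent")
    with pytest.raises(PreprocessError, match="quantile"):
        css_normalize(t, 1.5)


def test_normalization_state_rejects_nonpositive():
    with pytest.raises(PreprocessError):
        NormalizationState(0.5, 0.0)
    with pytest.raises(PreprocessError):
        NormalizationState(0.5, 1.0, {"s": -1.0})


# ---------------------------------------------------------------------------
# stratified splitting
# ---------------------------------------------------------------------------

def _cohort(n_a=60, n_b=40):
    mapping = {f"a{i}": "caseA" for i in range(n_a)}
    mapping.update({f"b{i}": "caseB" for i in range(n_b)})
    return SampleMetadata(mapping)


def test_split_exact_proportions():
    meta = _cohort()
    cfg = PreprocessConfig(test_fraction=0.15, validation_fraction=0.0, seed=1)
    split = stratified_split(meta, cfg)
    test_a = sum(1 for s in split.test_ids if s.startswith("a"))
    test_b = sum(1 for s in split.test_ids if s.startswith("b"))
    assert (test_a, test_b) == (9, 6)
    assert split.validation_ids == []
    assert sorted(split.train_ids + split.test_ids) == sorted(meta.mapping)


def test_split_deterministic():
    meta = _cohort()
    cfg = PreprocessConfig(seed=11)
    s1 = stratified_split(meta, cfg)
    s2 = stratified_split(meta, cfg)
    assert (s1.train_ids, s1.validation_ids, s1.test_ids) == (
        s2.train_ids,
        s2.validation_ids,
        s2.test_ids,
    )


def test_split_partitions_disjoint_exhaustive():
    meta = _cohort(23, 17)
    cfg = PreprocessConfig(test_fraction=0.2, validation_fraction=0.25, seed=3)
    split = stratified_split(meta, cfg)
    all_ids = split.train_ids + split.validation_ids + split.test_ids
    assert len(all_ids) == len(set(all_ids)) == 40


def test_split_class_proportion_within_one_sample():
    meta = _cohort(70, 30)
    cfg = PreprocessConfig(test_fraction=0.2, validation_fraction=0.1, seed=5)
    split = stratified_split(meta, cfg)
    for prefix, n_c in (("a", 70), ("b", 30)):
        n_test = sum(1 for s in split.test_ids if s.startswith(prefix))
        assert abs(n_test - 0.2 * n_c) < 1


def test_split_small_class_errors():
    meta = SampleMetadata({"x1": "a", "x2": "a", "x3": "a", "y1": "b", "y2": "b"})
    with pytest.raises(SplitError, match="'b'"):
        stratified_split(meta, PreprocessConfig(seed=0))


def test_config_validation():
    with pytest.raises(PreprocessError):
        PreprocessConfig(abundance_threshold=-1)
    with pytest.raises(PreprocessError):
        PreprocessConfig(test_fraction=1.5)
    with pytest.raises(PreprocessError):
        PreprocessConfig(validation_fraction=1.0)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def test_assemble_shape_and_labels():
    t = make_table(np.arange(6.0).reshape(2, 3), value_kind="relative_percent")
    meta = SampleMetadata({"s0": "healthy", "s1": "sick"})
    X, y = assemble_features(t, t.taxon_ids, meta)
    assert X.shape == (2, 3)
    np.testing.assert_array_equal(y, [0, 1])


def test_assemble_zero_fills_missing_taxa():
    t = make_table([[1.0, 2.0]], value_kind="relative_percent")
    retained = t.taxon_ids + ["k__B|p__P|c__C|o__O|f__F|g__G|s__Missing"]
    X, _ = assemble_features(t, retained)
    np.testing.assert_array_equal(X, [[1.0, 2.0, 0.0]])


def test_assemble_invariant_to_column_permutation():
    rng = np.random.default_rng(2)
    t = make_table(rng.uniform(0, 1, (3, 6)), value_kind="relative_percent")
    perm = t.select_taxa(list(rng.permutation(6)))
    X1, _ = assemble_features(t, t.taxon_ids)
    X2, _ = assemble_features(perm, t.taxon_ids)
    np.testing.assert_array_equal(X1, X2)
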