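"""Parsing, filter cascade, labels, vocabularies and stratified splits."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrspec import vdjdb_io as vio
from tcrspec.vdjdb_io import (Chain, ClassLabel, ColumnConfigurationError,
                              FilterConfig, GeneVocabulary, MHCClass, TCRRecord,
                              apply_filters, assign_class_labels,
                              build_gene_vocabulary, categorize_difficulty,
                              deduplicate, min_class_size_filter,
                              read_vdjdb_table, stratified_split)

from conftest import VDJDB_HEADER, make_row


def rec(**kw):
    base = dict(cdr3="CASSLG", chain=Chain.TRB, v_gene="TRBV1", j_gene="TRBJ1-1",
                mhc_a="HLA-A", mhc_b="B2M", mhc_class=MHCClass.MHCI,
                host_species="HomoSapiens", epitope_seq="NLVPMVATV",
                epitope_gene="pp65", epitope_species="CMV", confidence_score=2)
    base.update(kw)
    return TCRRecord(**base)


# ---------------------------------------------------------------- parsing

def test_read_round_trips_toy_table(toy_table):
    result = read_vdjdb_table(toy_table)
    assert len(result) == 3 and not result.errors
    r = result[0]
    assert (r.cdr3, r.v_gene, r.j_gene) == ("CASSLGETQYF", "TRBV7-9", "TRBJ2-5")
    assert r.chain is Chain.TRB and r.mhc_class is MHCClass.MHCI
    assert r.confidence_score == 2 and r.epitope_species == "CMV"


def test_read_header_only_gives_empty_list():
    result = read_vdjdb_table(io.StringIO(VDJDB_HEADER + "\n"))
    assert len(result) == 0 and not result.errors


def test_unparseable_score_goes_to_error_list_not_crash():
    text = VDJDB_HEADER + "\n" + make_row(score="x") + "\n" + make_row() + "\n"
    result = read_vdjdb_table(io.StringIO(text))
    assert len(result) == 1
    assert len(result.errors) == 1 and "confidence score" in result.errors[0].message


def test_non_canonical_cdr3_rejected_per_row():
    text = VDJDB_HEADER + "\n" + make_row(cdr3="CASS1XZ*") + "\n"
    result = read_vdjdb_table(io.StringIO(text))
    assert len(result) == 0 and len(result.errors) == 1


def test_missing_mandatory_column_is_configuration_error():
    text = "cdr3\tfoo\nCASS\tbar\n"
    with pytest.raises(ColumnConfigurationError):
        read_vdjdb_table(io.StringIO(text))


def test_records_to_frame_round_trip(toy_table):
    result = read_vdjdb_table(toy_table)
    frame = vio.records_to_frame(result.records)
    again = read_vdjdb_table(io.StringIO(frame.to_csv(sep="\t", index=False)))
    assert list(again) == list(result)


# ---------------------------------------------------------------- filters

def test_score_zero_removed_at_score_step():
    retained, report = apply_filters([rec(confidence_score=0)])
    assert retained == []
    d = dict(report.steps)
    assert d[vio.STEP_HOST] == 1 and d[vio.STEP_SCORE] == 0


def test_tra_removed_at_chain_step():
    retained, report = apply_filters([rec(chain=Chain.TRA)])
    assert retained == []
    d = dict(report.steps)
    assert d[vio.STEP_DEDUP] == 1 and d[vio.STEP_TRB] == 0


def test_empty_input_reports_every_step_zero():
    retained, report = apply_filters([])
    assert retained == []
    assert [s for s, _ in report.steps] == [
        vio.STEP_RAW, vio.STEP_NA, vio.STEP_HOST, vio.STEP_SCORE,
        vio.STEP_DENYLIST, vio.STEP_DEDUP, vio.STEP_TRB]
    assert all(r == 0 for _, r in report.steps)


def test_denylisted_epitope_species_removed():
    retained, report = apply_filters([rec(epitope_species="HomoSapiens"), rec()])
    assert len(retained) == 1
    assert dict(report.steps)[vio.STEP_DENYLIST] == 1


@given(st.lists(st.tuples(st.integers(0, 3), st.sampled_from(["TRA", "TRB"]),
                          st.sampled_from(["HomoSapiens", "MusMusculus", "Macaque"])),
                max_size=30))
@settings(deadline=None, max_examples=100)
def test_filter_report_monotone_non_increasing(rows):
    records = [rec(cdr3="CASS" + "ACDEF"[i % 5] * (i % 3 + 1),
                   confidence_score=s, chain=Chain(c), host_species=h)
               for i, (s, c, h) in enumerate(rows)]
    _, report = apply_filters(records)
    counts = [r for _, r in report.steps]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------- dedup

def test_duplicate_on_full_key_collapses_to_first():
    a = rec(mhc_class=MHCClass.MHCI)
    b = rec(mhc_class=MHCClass.MHCII)  # differs off-key only
    assert deduplicate([a, b]) == [a]


def test_same_cdr3_different_v_gene_both_kept():
    a, b = rec(), rec(v_gene="TRBV2")
    assert deduplicate([a, b]) == [a, b]


def test_deduplicate_idempotent_and_order_preserving():
    records = [rec(cdr3=c) for c in ("CASSA", "CASSD", "CASSA", "CASSC")]
    once = deduplicate(records)
    assert deduplicate(once) == once
    assert [r.cdr3 for r in once] == ["CASSA", "CASSD", "CASSC"]
    assert deduplicate([]) == []


# ---------------------------------------------------------------- labels

def test_class_label_is_space_joined_triple():
    labelled = assign_class_labels([rec(epitope_species="MCMV", epitope_gene="m139",
                                        epitope_seq="TVYGFCLL")])
    assert labelled[0][1].value == "MCMV m139 TVYGFCLL"
    assert ClassLabel("X", "Y", "Z").value == "X Y Z"


def test_records_sharing_triple_get_equal_labels():
    a, b = rec(cdr3="CASSA"), rec(cdr3="CASSD")
    (_, la), (_, lb) = assign_class_labels([a, b])
    assert la == lb


def test_empty_epitope_field_is_error():
    with pytest.raises(ValueError):
        assign_class_labels([rec(epitope_gene="")])


# ------------------------------------------------------- class-size filter

@pytest.mark.parametrize("n,min_n,kept", [(50, 50, True), (49, 50, False), (5, 1, True)])
def test_min_class_size_boundary(n, min_n, kept):
    labelled = assign_class_labels([rec(cdr3="CASS" + "ACDEFGHIKLMNPQRSTVWY"[i % 20]
                                        * (i // 20 + 1)) for i in range(n)])
    out = min_class_size_filter(labelled, min_n=min_n)
    assert (len(out) == n) is kept


@pytest.mark.parametrize("count,expected", [(101, "easy"), (99, "hard"), (100, "hard")])
def test_difficulty_boundary(count, expected):
    assert categorize_difficulty({"c": count})["c"] == expected


# ---------------------------------------------------------------- vocab

@pytest.mark.parametrize("n,table_size", [(63, 65), (13, 15), (1, 3)])
def test_vocabulary_table_size_formula(n, table_size):
    records = [rec(v_gene=f"TRBV{i}") for i in range(n)]
    vocab = build_gene_vocabulary(records, "v_gene")
    assert vocab.table_size == table_size
    assert vocab.padding_index == 0 and vocab.special_index == n + 1


def test_vocabulary_encode_decode_identity_and_unknown():
    vocab = GeneVocabulary(names=["TRBJ1-1", "TRBJ1-2"])
    for name in vocab.names:
        assert vocab.decode(vocab.encode(name)) == name
    assert vocab.encode("TRBJ9-9") == vocab.special_index
    assert GeneVocabulary.from_json(vocab.to_json()).index_of == vocab.index_of


# ---------------------------------------------------------------- split

@pytest.mark.parametrize("n,sizes", [(10, (7, 1, 2)), (20, (14, 3, 3))])
def test_split_floor_rule(n, sizes):
    split = stratified_split(["c"] * n, seed=3)
    got = tuple(len(split.ids(p)) for p in ("train", "validation", "test"))
    assert got == sizes


def test_split_deterministic_disjoint_exhaustive():
    labels = ["a"] * 10 + ["b"] * 7 + ["c"] * 23
    s1 = stratified_split(labels, seed=9)
    s2 = stratified_split(labels, seed=9)
    assert s1.partition == s2.partition
    ids = [set(s1.ids(p)) for p in ("train", "validation", "test")]
    assert ids[0] | ids[1] | ids[2] == set(range(len(labels)))
    assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])
    # per-class floor rule
    for lab, n in (("a", 10), ("b", 7), ("c", 23)):
        in_class = [i for i, l in enumerate(labels) if l == lab]
        tr = len(set(in_class) & ids[0])
        va = len(set(in_class) & ids[1])
        assert tr == int(np.floor(0.7 * n)) and va == int(np.floor(0.15 * n))


def test_split_rejects_tiny_class():
    with pytest.raises(ValueError, match="tiny"):
        stratified_split(["tiny", "tiny", "big", "big", "big"])
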