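"""Hierarchical class assignment, karyotype features and TP53 allelic state."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from amlclass import (
    AmlClass,
    LesionProfile,
    MutationCall,
    Tp53State,
    classify_cohort,
    classify_patient,
    derived_karyotype_features,
    load_hierarchy,
    tp53_allelic_state,
)
from amlclass.cohort import Consequence
from amlclass.vocab import get_lesion


def profile(lesions=(), genes=(), calls=(), **kwargs):
    muts = [MutationCall(g) for g in genes] + list(calls)
    return LesionProfile.build("t", mutations=muts, cytogenetics=lesions, **kwargs)


# -- karyotype features ------------------------------------------------------

@pytest.mark.parametrize(
    "lesions, n_unb, n_tri, has_del, complex_, monosomal",
    [
        (["del(5q)", "-7", "del(17p)"], 3, 0, True, True, True),
        (["t(8;21)"], 0, 0, False, False, False),
        (["+8", "+11", "+13", "+21"], 4, 4, False, False, False),
        ([], 0, 0, False, False, False),
        (["-7", "-17"], 2, 0, True, False, True),
        (["-7", "del(5q)"], 2, 0, True, False, True),
        (["+8", "del(7q)", "other_unbalanced"], 3, 1, True, True, False),
    ],
)
def test_derived_karyotype_features(lesions, n_unb, n_tri, has_del, complex_,
                                    monosomal):
    f = derived_karyotype_features(profile(lesions))
    assert f.n_unbalanced == n_unb
    assert f.n_trisomies == n_tri
    assert f.has_deletion == has_del
    assert f.is_complex == complex_
    assert f.is_monosomal == monosomal


# -- TP53 allelic state ------------------------------------------------------

def tp53(vaf):
    return MutationCall("TP53", vaf=vaf)


@pytest.mark.parametrize(
    "mutations, lesions, expected",
    [
        ([tp53(0.3), MutationCall("TP53", vaf=0.2, consequence=Consequence.INDEL)],
         [], Tp53State.MULTI_HIT),
        ([tp53(0.40)], [], Tp53State.MONO_ALLELIC),
        ([tp53(0.70)], [], Tp53State.MULTI_HIT),
        ([tp53(0.40)], ["del(17p)"], Tp53State.MULTI_HIT),
        ([tp53(0.40)], ["-17"], Tp53State.MULTI_HIT),
        ([tp53(None)], [], Tp53State.MONO_ALLELIC),  # no VAF: LOH rule silent
        ([], ["del(17p)"], Tp53State.WILD_TYPE),
        ([tp53(0.65)], [], Tp53State.MONO_ALLELIC),  # strictly greater than 65%
    ],
)
def test_tp53_allelic_state(mutations, lesions, expected):
    cyto = [get_lesion(c) for c in lesions]
    assert tp53_allelic_state(mutations, cyto) is expected
    # order independence
    assert tp53_allelic_state(reversed(mutations), reversed(cyto)) is expected


# -- hierarchy examples ------------------------------------------------------

@pytest.mark.parametrize(
    "lesions, genes, expected",
    [
        ([], ["BCOR", "SF3B1"], AmlClass.sAML2),
        ([], [], AmlClass.no_events),
        (["t(15;17)"], ["SRSF2", "ASXL1"], AmlClass.APL_t15_17),
        ([], ["SRSF2"], AmlClass.sAML1),
        ([], ["SRSF2", "ASXL1"], AmlClass.sAML2),
        (["del(5q)", "-7", "del(17p)"], [], AmlClass.TP53_complex),
        ([], ["TP53"], AmlClass.TP53_complex),
        (["+8", "+13"], [], AmlClass.trisomies),
        (["+8", "del(5q)"], [], AmlClass.mNOS),  # gains with deletion: no class
        ([], ["DNMT3A", "IDH1"], AmlClass.DNMT3A_IDH),
        ([], ["DNMT3A"], AmlClass.mNOS),
        ([], ["WT1"], AmlClass.WT1),
        (["t(8;21)"], ["WT1"], AmlClass.t8_21),  # WT1 yields to classifying events
        ([], ["NRAS"], AmlClass.mNOS),
        (["inv(3)", "-7"], [], AmlClass.inv3),
        (["t(6;9)"], [], AmlClass.t6_9),
        (["t(11;x)"], [], AmlClass.KMT2A_t11x),
    ],
)
def test_class_assignment_examples(lesions, genes, expected):
    assert classify_patient(profile(lesions, genes)).aml_class is expected


def test_npm1_with_itd_and_dnmt3a_is_npm1_class():
    p = profile(
        genes=["NPM1", "DNMT3A"],
        calls=[MutationCall("FLT3", consequence=Consequence.ITD)],
    )
    a = classify_patient(p)
    assert a.aml_class is AmlClass.NPM1
    assert a.evidence == {"NPM1"}


def test_bicebpa_requires_two_distinct_calls():
    single = profile(calls=[MutationCall("CEBPA", vaf=0.4)])
    assert classify_patient(single).aml_class is AmlClass.mNOS
    double = profile(calls=[
        MutationCall("CEBPA", vaf=0.4),
        MutationCall("CEBPA", vaf=0.3, consequence=Consequence.INDEL),
    ])
    assert classify_patient(double).aml_class is AmlClass.biCEBPA


def test_mll_ptd_counts_as_saml_feature_but_other_mll_does_not():
    ptd = profile(calls=[MutationCall("MLL", consequence=Consequence.PTD),
                         MutationCall("SRSF2")])
    assert classify_patient(ptd).aml_class is AmlClass.sAML2
    sub = profile(calls=[MutationCall("MLL"), MutationCall("SRSF2")])
    assert classify_patient(sub).aml_class is AmlClass.sAML1


@pytest.mark.parametrize("k", range(1, 12))
def test_saml_threshold_one_vs_two_or_more(k, panel):
    feats = sorted(panel.saml_class_defining)[:k]
    calls = [
        MutationCall("MLL", consequence=Consequence.PTD) if f == "MLL-PTD"
        else MutationCall(f)
        for f in feats
    ]
    expected = AmlClass.sAML1 if k == 1 else AmlClass.sAML2
    assert classify_patient(profile(calls=calls)).aml_class is expected


def test_first_match_semantics_removing_evidence_moves_later():
    p = profile(["t(15;17)"], ["SRSF2", "ASXL1"])
    a = classify_patient(p)
    assert a.aml_class is AmlClass.APL_t15_17
    stripped = profile([], ["SRSF2", "ASXL1"])
    b = classify_patient(stripped)
    assert b.rule_rank > a.rule_rank and b.aml_class is AmlClass.sAML2


def test_evidence_nonempty_except_no_events():
    assert classify_patient(profile()).evidence == frozenset()
    for lesions, genes in [(["inv(16)"], []), ([], ["NPM1"]), ([], ["NRAS"])]:
        assert classify_patient(profile(lesions, genes)).evidence


_UNIVERSE_LESIONS = ["t(15;17)", "inv(16)", "t(11;x)", "del(5q)", "-7", "+8"]
_UNIVERSE_GENES = ["TP53", "NPM1", "SRSF2", "ASXL1", "DNMT3A", "IDH1", "WT1"]


@settings(max_examples=300, deadline=None)
@given(
    lmask=st.integers(0, 2 ** len(_UNIVERSE_LESIONS) - 1),
    gmask=st.integers(0, 2 ** len(_UNIVERSE_GENES) - 1),
    itd=st.booleans(),
)
def test_totality_and_itd_neutrality_property(lmask, gmask, itd):
    """Any lesion/gene subset gets exactly one class; FLT3-ITD never
    changes it."""
    lesions = [c for i, c in enumerate(_UNIVERSE_LESIONS) if lmask >> i & 1]
    genes = [g for i, g in enumerate(_UNIVERSE_GENES) if gmask >> i & 1]
    calls = [MutationCall("FLT3", consequence=Consequence.ITD)] if itd else []
    a = classify_patient(profile(lesions, genes, calls))
    b = classify_patient(profile(lesions, genes))
    assert a.aml_class is b.aml_class
    assert a.aml_class in AmlClass


def test_classify_cohort_fractions_sum_to_one():
    profiles = [
        LesionProfile.build(f"p{i}", mutations=[MutationCall("NPM1")])
        for i in range(10)
    ]
    table, summary = classify_cohort(profiles)
    assert len(table) == 10
    npm1 = summary.set_index("class").loc["NPM1"]
    assert npm1["count"] == 10 and npm1["fraction"] == 1.0
    assert summary["fraction"].sum() == pytest.approx(1.0)


def test_classify_cohort_empty_input():
    table, summary = classify_cohort([])
    assert len(table) == 0
    assert summary["count"].sum() == 0


def test_hierarchy_config_validation(tmp_path):
    assert len(load_hierarchy()) == 16
    bad = tmp_path / "h.yaml"
    bad.write_text("order: [NPM1, no_events]\n")
    with pytest.raises(ValueError):
        load_hierarchy(bad)


def test_missing_karyotype_treated_as_no_cytogenetic_lesions():
    p = LesionProfile.build("x", mutations=[MutationCall("NRAS")],
                            karyotype_available=False)
    assert classify_patient(p).aml_class is AmlClass.mNOS
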