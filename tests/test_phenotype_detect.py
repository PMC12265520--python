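import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacomplete.phenotype_detect import (
    AgeForm,
    AgeUnit,
    Status,
    annotate_sample,
    detect_age,
    detect_organism,
    detect_rea,
    detect_sex,
    detect_strain,
    detect_tissue,
    parse_age_value,
)
from metacomplete.records import CharacteristicField, Origin, SampleRecord


def sample_with(characteristics, organism="Homo sapiens", source="", **kwargs):
    fields = []
    if organism:
        fields.append(CharacteristicField("", organism, Origin.organism_element))
    if source:
        fields.append(CharacteristicField("", source, Origin.source_element))
    fields += [
        CharacteristicField(tag, value, Origin.characteristics_element)
        for tag, value in characteristics
    ]
    return SampleRecord(
        accession="GSM1",
        organism_raw=organism or None,
        source_name=source,
        characteristics=fields,
        **kwargs,
    )


class TestOrganism:
    def test_canonical_name_passes_through(self, vocab):
        det = detect_organism(sample_with([], organism="Homo sapiens"), vocab)
        assert det.status is Status.available
        assert det.normalized_value == "Homo sapiens"
        assert not det.non_canonical

    def test_case_is_normalized(self, vocab):
        det = detect_organism(sample_with([], organism="mus musculus"), vocab)
        assert det.normalized_value == "Mus musculus"

    def test_absent_is_missing(self, vocab):
        det = detect_organism(sample_with([], organism=""), vocab)
        assert det.status is Status.missing

    def test_unknown_binomial_passes_verbatim_flagged(self, vocab):
        det = detect_organism(sample_with([], organism="Vulpes vulpes"), vocab)
        assert det.status is Status.available
        assert det.normalized_value == "Vulpes vulpes"
        assert det.non_canonical


class TestSex:
    @pytest.mark.parametrize(
        "tag,value,label",
        [
            ("sex", "F", "female"),
            ("gender", "Male", "male"),
            ("sex", "female", "female"),
            ("sex/gender", "M", "male"),
            ("sex", "pooled", "mixed"),
            ("sex", "2F, 1M", "mixed"),
        ],
    )
    def test_tagged_values(self, vocab, tag, value, label):
        det = detect_sex(sample_with([(tag, value)]), vocab)
        assert det.status is Status.available
        assert det.normalized_value == label
        assert det.provenance is not None

    @pytest.mark.parametrize("token", ["N/A", "unknown", "not collected", "--"])
    def test_missing_tokens_do_not_count(self, vocab, token):
        assert detect_sex(sample_with([("sex", token)]), vocab).status is Status.missing

    def test_untagged_inline_value(self, vocab):
        det = detect_sex(sample_with([("", "Sex: F")]), vocab)
        assert det.status is Status.available
        assert det.normalized_value == "female"

    def test_conflict_flagged_first_match_wins(self, vocab):
        det = detect_sex(sample_with([("sex", "F"), ("gender", "male")]), vocab)
        assert det.normalized_value == "female"
        assert det.conflict


class TestAge:
    # hand-written regex oracle table: raw -> (form, unit, magnitude/low/high)
    @pytest.mark.parametrize(
        "raw,form,unit,nums",
        [
            ("45", AgeForm.point, AgeUnit.unspecified, (45.0,)),
            ("45-50", AgeForm.range, AgeUnit.unspecified, (45.0, 50.0)),
            ("45 - 50 years", AgeForm.range, AgeUnit.year, (45.0, 50.0)),
            (">60", AgeForm.bound, AgeUnit.unspecified, (60.0,)),
            ("65+", AgeForm.bound, AgeUnit.unspecified, (65.0,)),
            ("6 weeks", AgeForm.point, AgeUnit.week, (6.0,)),
            ("12 months", AgeForm.point, AgeUnit.month, (12.0,)),
            ("3 days", AgeForm.point, AgeUnit.day, (3.0,)),
            ("E14.5", AgeForm.point, AgeUnit.embryonic_day, (14.5,)),
            ("72 hrs", AgeForm.point, AgeUnit.hour, (72.0,)),
            ("adult", AgeForm.stage, AgeUnit.unspecified, ()),
        ],
    )
    def test_parse_table(self, raw, form, unit, nums):
        age = parse_age_value(raw)
        assert age.form is form
        assert age.unit is unit
        if form is AgeForm.range:
            assert (age.low, age.high) == nums
        elif nums:
            assert age.magnitude == nums[0]

    def test_unit_from_tag(self, vocab):
        det = detect_age(sample_with([("age (yrs)", "45")]), vocab)
        assert det.normalized_value.unit is AgeUnit.year

    def test_unparseable_value_counts_as_available_stage(self, vocab):
        det = detect_age(sample_with([("developmental stage", "larval")]), vocab)
        assert det.status is Status.available
        assert det.normalized_value.form is AgeForm.stage
        assert det.normalized_value.stage_label == "larval"

    def test_missing_token_is_missing(self, vocab):
        assert detect_age(sample_with([("age", "unknown")]), vocab).status is Status.missing


class TestTissue:
    def test_tag_beats_source(self, vocab):
        det = detect_tissue(sample_with([("tissue", "whole blood")], source="liver"), vocab)
        assert det.normalized_value == "blood"

    def test_source_element_counts(self, vocab):
        det = detect_tissue(sample_with([], source="liver biopsy"), vocab)
        assert det.status is Status.available
        assert det.provenance.origin is Origin.source_element

    def test_missing_when_tag_is_token_and_source_empty(self, vocab):
        det = detect_tissue(sample_with([("tissue", "n/a")]), vocab)
        assert det.status is Status.missing

    def test_vocabulary_scan_of_untagged_text(self, vocab):
        det = detect_tissue(sample_with([("", "bone marrow")]), vocab)
        assert det.status is Status.available
        assert det.normalized_value == "bone marrow"


class TestStrainAndRea:
    def test_strain_available_for_mouse(self, vocab):
        det = detect_strain(
            sample_with([("strain", "C57BL/6J")], organism="Mus musculus"),
            vocab, is_human=False,
        )
        assert det.status is Status.available
        assert det.normalized_value == "C57BL/6J"

    def test_strain_not_applicable_for_human(self, vocab):
        det = detect_strain(
            sample_with([("strain", "C57BL/6J")]), vocab, is_human=True
        )
        assert det.status is Status.not_applicable

    def test_rea_harmonized_to_ancestry_category(self, vocab):
        det = detect_rea(sample_with([("ethnicity", "Caucasian")]), vocab, is_human=True)
        assert det.normalized_value == "European"

    def test_rea_not_applicable_for_mouse_even_with_content(self, vocab):
        det = detect_rea(
            sample_with([("race", "n/a")], organism="Mus musculus"),
            vocab, is_human=False,
        )
        assert det.status is Status.not_applicable

    def test_rea_missing_token(self, vocab):
        det = detect_rea(sample_with([("race", "not collected")]), vocab, is_human=True)
        assert det.status is Status.missing


class TestAnnotate:
    def test_full_human_sample(self, vocab):
        s = sample_with(
            [("sex", "F"), ("age", "41"), ("tissue", "whole blood"),
             ("ethnicity", "White")],
        )
        p = annotate_sample(s, vocab)
        assert p.is_human
        statuses = {a: d.status for a, d in p.detections.items()}
        assert statuses["strain"] is Status.not_applicable
        assert all(
            statuses[a] is Status.available
            for a in ("organism", "tissue", "sex", "age", "rea")
        )

    def test_mouse_with_only_organism(self, vocab):
        p = annotate_sample(sample_with([], organism="Mus musculus"), vocab)
        assert not p.is_human
        assert p.detections["organism"].status is Status.available
        assert p.detections["rea"].status is Status.not_applicable
        for attr in ("tissue", "sex", "age", "strain"):
            assert p.detections[attr].status is Status.missing

    def test_applicability_depends_only_on_organism(self, vocab):
        # same characteristic content, different organism
        chars = [("strain", "C57BL/6J"), ("race", "White")]
        human = annotate_sample(sample_with(chars), vocab)
        mouse = annotate_sample(sample_with(chars, organism="Mus musculus"), vocab)
        assert human.detections["strain"].status is Status.not_applicable
        assert human.detections["rea"].status is Status.available
        assert mouse.detections["strain"].status is Status.available
        assert mouse.detections["rea"].status is Status.not_applicable


@settings(max_examples=50, deadline=None)
@given(
    tag=st.sampled_from(["sex", "age", "tissue", "strain", "race", "note"]),
    value=st.text(
        alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd", "Zs")),
        max_size=20,
    ),
    organism=st.sampled_from(["Homo sapiens", "Mus musculus", None]),
)
def test_detectors_are_pure_and_provenance_backed(tag, value, organism):
    """Same input gives same output, and every 'available' verdict carries
    provenance (no unexplained detections)."""
    from metacomplete.vocab import default_vocabulary

    vocab = default_vocabulary()
    s = sample_with([(tag, value)], organism=organism or "")
    p1 = annotate_sample(s, vocab)
    p2 = annotate_sample(s, vocab)
    for attr, det in p1.detections.items():
        assert det.status == p2.detections[attr].status
        assert det.normalized_value == p2.detections[attr].normalized_value
        if det.status is Status.available:
            assert det.provenance is not None
        else:
            assert det.normalized_value is None
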