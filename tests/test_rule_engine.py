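import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_report
from neurofind.corpus_io import Label
from neurofind.rule_engine import (
    Category,
    Chronicity,
    Concept,
    Experiencer,
    SectionKind,
    Sentence,
    Status,
    Temporality,
    assign_context,
    classify_report,
    default_cues,
    default_lexicon,
    detect_sections,
    extract_mentions,
    match_concepts,
    rejoin_hyphenated_linebreaks,
    segment_sentences,
    summarize_document,
)

LEX = default_lexicon()
CUES = default_cues()


def sentence_of(text: str) -> Sentence:
    return Sentence(report_id="r1", index=0, start=0, end=len(text), text=text)


def mentions_of(text: str):
    return match_concepts(sentence_of(text), LEX)


def resolved_mentions(text: str):
    s = sentence_of(text)
    raw = match_concepts(s, LEX)
    return [assign_context(m, s, raw, CUES) for m in raw]


class TestSegmentation:
    def test_two_terminated_statements(self):
        sents = segment_sentences("No acute infarct. Chronic lacune in left basal ganglia.")
        assert len(sents) == 2
        assert sents[0].text == "No acute infarct."

    def test_single_sentence_no_terminal_period(self):
        text = "stable chronic lacunar infarct"
        [s] = segment_sentences(text)
        assert (s.start, s.end) == (0, len(text))

    def test_enumeration_does_not_split_empty(self):
        sents = segment_sentences("IMPRESSION: 1. No acute infarct.")
        assert all(s.text.strip() for s in sents)
        assert len(sents) == 1  # "1." is an enumeration marker, not a boundary

    def test_abbreviation_safe(self):
        sents = segment_sentences("Stable vs. slightly smaller lesion. No change.")
        assert len(sents) == 2

    def test_offsets_reconstruct_text(self):
        text = "FINDINGS:\nNo acute infarct. Old lacune.\nIMPRESSION: stable."
        sents = segment_sentences(text)
        for s in sents:
            assert text[s.start : s.end] == s.text
        for a, b in zip(sents, sents[1:]):
            assert a.end <= b.start  # ordered, non-overlapping
            assert text[a.end : b.start].strip() == ""  # gaps are whitespace

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            segment_sentences("   ")


class TestSections:
    def test_headerless_all_other(self):
        text = "No acute infarct. Old lacune."
        sents = detect_sections(segment_sentences(text), text)
        assert all(s.section is SectionKind.OTHER for s in sents)

    def test_partitioned_by_position(self):
        text = "FINDINGS:\nNo acute infarct.\nIMPRESSION:\nOld lacune."
        sents = detect_sections(segment_sentences(text), text)
        sections = [s.section for s in sents]
        assert sections[0] is SectionKind.FINDINGS
        assert sections[1] is SectionKind.FINDINGS
        assert sections[2] is SectionKind.IMPRESSION
        assert sections[3] is SectionKind.IMPRESSION

    def test_mid_line_header_does_not_switch(self):
        text = "FINDINGS:\nPlease see impression above for details."
        sents = detect_sections(segment_sentences(text), text)
        assert all(s.section is SectionKind.FINDINGS for s in sents)


class TestDefaultLexicon:
    def test_lacunes_is_sbi_finding(self):
        cats = {e.surface: e.category for e in LEX}
        assert cats["lacunes"] is Category.SBI_FINDING

    def test_degenerative_changes_is_wmd_exclusion(self):
        cats = {e.surface: e.category for e in LEX}
        assert cats["degenerative changes"] is Category.WMD_EXCLUSION

    def test_stroke_absent(self):
        assert "stroke" not in {e.surface for e in LEX}

    def test_expected_category_sizes(self):
        by_cat = {}
        for e in LEX:
            by_cat.setdefault(e.category, set()).add(e.surface)
        assert len(by_cat[Category.SBI_FINDING]) == 6
        assert len(by_cat[Category.SBI_MODIFIER_ACUTE] | by_cat[Category.SBI_MODIFIER_CHRONIC]) == 12
        assert len(by_cat[Category.WMD_FINDING]) == 5
        assert by_cat[Category.WMD_EXCLUSION] == {"degenerative changes"}


class TestMatchConcepts:
    def test_worked_example_mentions(self):
        ms = mentions_of("probable right old frontal lobe subcortical infarct as described above")
        by_cat = {m.category: m.surface_text for m in ms}
        assert by_cat[Category.SBI_FINDING] == "infarct"
        assert by_cat[Category.SBI_MODIFIER_CHRONIC] == "old"
        assert by_cat[Category.SBI_LOCATION] == "frontal"

    def test_confounder_sentence_no_findings(self):
        ms = mentions_of(
            "bilateral intraparenchymal foci of susceptibility artifact in the "
            "right occipital lobe"
        )
        assert all(m.category is not Category.SBI_FINDING for m in ms)

    def test_longest_match_wins(self):
        ms = mentions_of("chronic infarction noted")
        finding = [m for m in ms if m.category is Category.SBI_FINDING]
        assert [m.surface_text for m in finding] == ["infarction"]

    def test_multiword_modifier_longest(self):
        ms = mentions_of("acute or subacute infarct")
        mods = [m.surface_text for m in ms if m.category is Category.SBI_MODIFIER_ACUTE]
        assert mods == ["acute or subacute"]

    def test_case_insensitive_word_boundary(self):
        assert any(m.surface_text == "Infarct" for m in mentions_of("Infarct."))
        assert mentions_of("postinfarction cardiomyopathy") == [] or all(
            m.category is not Category.SBI_FINDING
            for m in mentions_of("postinfarction cardiomyopathy")
        )

    def test_exclusion_suppresses_adjacent_wmd_finding(self):
        ms = mentions_of("white matter degenerative changes")
        assert all(m.category is not Category.WMD_FINDING for m in ms)

    def test_wmd_finding_without_exclusion_survives(self):
        ms = mentions_of("scattered white matter signal changes")
        assert any(m.category is Category.WMD_FINDING for m in ms)

    def test_span_slices_reproduce_lexicon_surface(self):
        surfaces = {" ".join(e.surface.lower().split()) for e in LEX}
        for text in (
            "Chronic lacunar infarct, left basal ganglia.",
            "acute or subacute infarction in the right frontal lobe",
            "severe white matter microvascular ischemic changes",
        ):
            for m in mentions_of(text):
                assert " ".join(m.surface_text.lower().split()) in surfaces


class TestAssignContext:
    def test_worked_example_attributes(self):
        ms = resolved_mentions(
            "probable right old frontal lobe subcortical infarct as described above"
        )
        [finding] = [m for m in ms if m.category is Category.SBI_FINDING]
        assert finding.status is Status.PROBABLE
        assert finding.temporality is Temporality.PRESENT
        assert finding.experiencer is Experiencer.PATIENT
        assert finding.chronicity is Chronicity.CHRONIC

    def test_direct_negation_and_acute(self):
        ms = resolved_mentions("No acute infarct.")
        [finding] = [m for m in ms if m.category is Category.SBI_FINDING]
        assert finding.status is Status.NEGATED
        assert finding.chronicity is Chronicity.ACUTE

    def test_but_terminates_negation_scope(self):
        ms = resolved_mentions("No acute infarct, but chronic lacune in the left basal ganglia.")
        by_surface = {m.surface_text: m for m in ms if m.category is Category.SBI_FINDING}
        assert by_surface["infarct"].status is Status.NEGATED
        assert by_surface["lacune"].status is Status.CONFIRMED
        assert by_surface["lacune"].chronicity is Chronicity.CHRONIC

    def test_history_cue(self):
        ms = resolved_mentions("History of remote infarct.")
        [finding] = [m for m in ms if m.category is Category.SBI_FINDING]
        assert finding.temporality is Temporality.HISTORICAL

    def test_hypothetical_cue(self):
        ms = resolved_mentions("if there were an infarct here")
        [finding] = [m for m in ms if m.category is Category.SBI_FINDING]
        assert finding.temporality is Temporality.HYPOTHETICAL

    def test_experiencer_cue(self):
        ms = resolved_mentions("family history of infarction")
        [finding] = [m for m in ms if m.category is Category.SBI_FINDING]
        assert finding.experiencer is Experiencer.OTHER

    def test_defaults_when_no_cue(self):
        ms = resolved_mentions("Chronic lacune in the left basal ganglia.")
        [finding] = [m for m in ms if m.category is Category.SBI_FINDING]
        assert finding.status is Status.CONFIRMED
        assert finding.temporality is Temporality.PRESENT
        assert finding.experiencer is Experiencer.PATIENT

    def test_negation_outranks_hedge(self):
        ms = resolved_mentions("no possible infarct")
        [finding] = [m for m in ms if m.category is Category.SBI_FINDING]
        assert finding.status is Status.NEGATED


class TestSummarize:
    def _classify(self, text):
        return classify_report(make_report(text))

    def test_worked_example_document_indeterminate(self):
        dc = self._classify("probable right old frontal lobe subcortical infarct as described above.")
        assert dc.sbi_label is Label.INDETERMINATE
        assert len(dc.evidence) >= 1

    def test_negated_acute_only_negative(self):
        dc = self._classify("No acute infarction.")
        assert dc.sbi_label is Label.NEGATIVE and dc.wmd_label is Label.NEGATIVE

    def test_precedence_ladder_positive_both(self):
        dc = self._classify(
            "Chronic lacunar infarct, left basal ganglia. "
            "Moderate white matter microvascular ischemic changes."
        )
        assert dc.sbi_label is Label.POSITIVE and dc.wmd_label is Label.POSITIVE

    def test_acute_only_is_negative(self):
        dc = self._classify("Acute infarct in the left MCA territory.")
        assert dc.sbi_label is Label.NEGATIVE

    def test_historical_only_is_negative(self):
        dc = self._classify("History of remote infarct in the right frontal lobe.")
        assert dc.sbi_label is Label.NEGATIVE

    def test_confirmed_wins_over_negated(self):
        dc = self._classify("No acute infarct. Chronic lacune in the left basal ganglia.")
        assert dc.sbi_label is Label.POSITIVE

    def test_positive_evidence_satisfies_predicate(self):
        dc = self._classify("Old infarct in the right caudate nucleus.")
        assert dc.sbi_label is Label.POSITIVE
        for m in dc.evidence:
            assert m.status is Status.CONFIRMED
            assert m.temporality is Temporality.PRESENT
            assert m.experiencer is Experiencer.PATIENT
            assert m.chronicity in (Chronicity.CHRONIC, Chronicity.UNSPECIFIED)

    def test_impression_only_flag(self):
        text = "FINDINGS:\nChronic lacune in the left basal ganglia.\nIMPRESSION:\nUnremarkable."
        report = make_report(text)
        assert classify_report(report).sbi_label is Label.POSITIVE
        assert classify_report(report, impression_only=True).sbi_label is Label.NEGATIVE


BOX2_TEXT = (
    "Scattered, nonspecific T2 foci, most prominently in the left parietal white "
    "matter where there is an associated region of nonenhancing encephalomalacia "
    "and linear hemosiderin disposition. Linear hemosiderin deposition overlying "
    "the right temporal lobe (series 9, image 16) as well. No abnormal "
    "enhancement today. The above findings are nonspecific but the evolution, "
    "hemosiderin deposition, and gliosis suggest post ischemic change."
)


class TestClassifyReport:
    def test_coreference_split_is_known_false_negative(self):
        # The document implies a prior infarct only across sentences; without
        # coreference resolution the engine must (and does) miss it.
        dc = classify_report(make_report(BOX2_TEXT))
        assert dc.sbi_label is Label.NEGATIVE

    def test_empty_lexicon(self):
        dc = classify_report(make_report("Chronic infarct."), lexicon=[])
        assert dc.sbi_label is Label.NEGATIVE
        assert dc.wmd_label is Label.NEGATIVE
        assert dc.evidence == ()

    def test_deterministic(self):
        r = make_report("Chronic lacune in the left basal ganglia. No acute infarct.")
        assert classify_report(r) == classify_report(r)

    def test_hyphen_linewrap_rejoined(self):
        assert rejoin_hyphenated_linebreaks("infarc-\ntion") == "infarction"
        dc = classify_report(make_report("Chronic lacunar infarc-\ntion, left basal ganglia."))
        assert dc.sbi_label is Label.POSITIVE


class TestInvariants:
    NEGATIVE_TEXTS = [
        "No acute infarct.",
        "Unremarkable examination of the brain.",
        "History of remote infarction.",
        "FINDINGS:\nNo evidence of acute or subacute infarct.\nIMPRESSION:\nNormal.",
    ]

    @pytest.mark.parametrize("text", NEGATIVE_TEXTS)
    def test_adding_confirmed_chronic_finding_flips_positive(self, text):
        base = classify_report(make_report(text))
        assert base.sbi_label is Label.NEGATIVE
        extended = classify_report(
            make_report(text + "\nChronic lacune in the left basal ganglia.")
        )
        assert extended.sbi_label is Label.POSITIVE

    @pytest.mark.parametrize(
        "text",
        [
            "No acute infarct.",
            "Chronic lacune in the left basal ganglia.",
            "probable right old frontal lobe subcortical infarct as described above.",
            "Moderate white matter microvascular ischemic changes.",
        ],
    )
    def test_location_only_sentences_never_change_labels(self, text):
        base = classify_report(make_report(text))
        extended = classify_report(
            make_report(
                text + "\nFoci of artifact in the right occipital lobe, right "
                "parietal lobe, right subinsular region and left frontal region."
            )
        )
        assert (base.sbi_label, base.wmd_label) == (extended.sbi_label, extended.wmd_label)

    def test_matching_completeness_each_term_recalled(self):
        # each lexicon term embedded once in a neutral carrier sentence
        for entry in LEX:
            text = f"The report describes {entry.surface} in this study."
            ms = mentions_of(text)
            assert any(
                m.matched_entry.surface == entry.surface
                or (
                    m.matched_entry.category is entry.category
                    and entry.surface in m.surface_text.lower()
                )
                for m in ms
            ), entry.surface

    def test_offsets_reproduce_surfaces(self, small_corpus):
        surfaces = {" ".join(e.surface.lower().split()) for e in LEX}
        for bundle in small_corpus[:50]:
            for m in extract_mentions(bundle.report):
                assert " ".join(m.surface_text.lower().split()) in surfaces

    @given(st.text(alphabet="abc .\n", min_size=1).filter(lambda t: t.strip()))
    @settings(max_examples=60, deadline=None)
    def test_segmentation_spans_are_ordered_substrings(self, text):
        sents = segment_sentences(text)
        prev_end = 0
        for s in sents:
            assert s.start >= prev_end
            assert text[s.start : s.end] == s.text
            prev_end = s.end
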