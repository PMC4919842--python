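import random

import pytest

from semschema.context_engine import (
    apply_modifiers,
    compile_lexicon,
    default_category_resolver,
    match_targets,
    segment_sentences,
    write_knowtator_xml,
)
from semschema.nlp_export import LexiconEntry

from oracles import brute_force_match, brute_force_modifiers

TARGETS = compile_lexicon(
    [
        LexiconEntry("occlusion", "occlusion"),
        LexiconEntry("stenosis", "stenosis"),
        LexiconEntry("internal carotid artery occlusion", "occlusion"),
        LexiconEntry("ica", "internal_carotid_artery"),
    ]
)

MODIFIERS = compile_lexicon(
    [
        LexiconEntry("no", "Definite_Negated_Existence", rule="forward"),
        LexiconEntry("ruled out", "Definite_Negated_Existence", rule="backward"),
        LexiconEntry("mild", "Mild_Severity", rule="bidirectional"),
        LexiconEntry("left", "Left_Body_Side", rule="bidirectional"),
        LexiconEntry("but", "TERMINATE", rule="terminate"),
    ]
)


class TestSegmentation:
    def test_two_terminators(self):
        text = "No occlusion. ICA is patent."
        spans = segment_sentences(text)
        assert len(spans) == 2
        assert text[spans[0][0] : spans[0][1]].strip() == "No occlusion."

    def test_empty_string(self):
        assert segment_sentences("") == []

    def test_abbreviation_guard(self):
        assert len(segment_sentences("Dr. Smith notes stenosis.")) == 1
        assert len(segment_sentences("Seen by Dr. Smith. Stenosis noted.")) == 2

    def test_newline_runs_break_sentences(self):
        assert len(segment_sentences("no occlusion\n\nmild stenosis")) == 2

    @pytest.mark.parametrize(
        "text",
        [
            "One. Two! Three?",
            "no terminator at all",
            "trailing spaces.   ",
            "a.b. odd, e.g. this. done.",
            "multi\nline\n\ntext here",
        ],
    )
    def test_spans_tile_text(self, text):
        spans = segment_sentences(text)
        assert spans[0][0] == 0 and spans[-1][1] == len(text)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 == s2


class TestMatchTargets:
    def test_longest_match_wins(self):
        text = "internal carotid artery occlusion"
        mentions = match_targets(text, (0, len(text)), TARGETS)
        assert len(mentions) == 1
        assert mentions[0].text == text
        assert mentions[0].category == "occlusion"

    def test_no_hit(self):
        text = "entirely unrelated sentence"
        assert match_targets(text, (0, len(text)), TARGETS) == []

    def test_mention_text_equals_slice(self):
        text = "mild stenosis and ICA occlusion"
        for m in match_targets(text, (0, len(text)), TARGETS):
            assert text[m.span[0] : m.span[1]] == m.text

    def test_order_independence(self):
        text = "internal carotid artery occlusion but stenosis"
        reversed_lexicon = compile_lexicon(list(reversed(TARGETS.entries)))
        assert match_targets(text, (0, len(text)), TARGETS) == match_targets(
            text, (0, len(text)), reversed_lexicon
        )


class TestApplyModifiers:
    def _annotate(self, text):
        mentions = match_targets(text, (0, len(text)), TARGETS)
        resolver = default_category_resolver()
        return apply_modifiers(text, (0, len(text)), mentions, MODIFIERS, resolver)

    def test_simple_negation(self):
        annotated = self._annotate("no occlusion")
        assert annotated[0].modifier_map() == {"Certainty": "Definite_Negated_Existence"}

    def test_forward_cue_respects_position(self):
        annotated = self._annotate("occlusion and no stenosis")
        by_cat = {a.mention.category: a.modifier_map() for a in annotated}
        assert "Certainty" not in by_cat["occlusion"]
        assert by_cat["stenosis"] == {"Certainty": "Definite_Negated_Existence"}

    def test_backward_cue(self):
        annotated = self._annotate("occlusion was ruled out")
        assert annotated[0].modifier_map()["Certainty"] == "Definite_Negated_Existence"

    def test_terminate_cuts_scope(self):
        annotated = self._annotate("no stenosis but occlusion is present")
        by_cat = {a.mention.category: a.modifier_map() for a in annotated}
        assert by_cat["stenosis"] == {"Certainty": "Definite_Negated_Existence"}
        assert "Certainty" not in by_cat["occlusion"]

    def test_nearest_cue_per_category_wins(self):
        text = "mild left ica"
        annotated = self._annotate(text)
        assert annotated[0].modifier_map() == {
            "Severity": "Mild_Severity",
            "Body Side": "Left_Body_Side",
        }


class TestBruteForceEquivalence:
    VOCAB = [
        "no", "mild", "left", "but", "ica", "occlusion", "stenosis",
        "ruled", "out", "ruled out", "artery", "the", "is", "patent",
        "internal", "carotid",
    ]

    def test_matching_equivalence_on_random_sentences(self):
        rng = random.Random(42)
        for _ in range(300):
            words = [rng.choice(self.VOCAB) for _ in range(rng.randint(1, 6))]
            text = " ".join(words)
            span = (0, len(text))
            got = sorted((m.span[0], m.span[1], m.category)
                         for m in match_targets(text, span, TARGETS))
            assert got == brute_force_match(text, span, TARGETS.entries)

    def test_scoping_equivalence_on_random_sentences(self):
        rng = random.Random(43)
        resolver = default_category_resolver()
        for _ in range(300):
            words = [rng.choice(self.VOCAB) for _ in range(rng.randint(1, 6))]
            text = " ".join(words)
            span = (0, len(text))
            mentions = match_targets(text, span, TARGETS)
            annotated = apply_modifiers(text, span, mentions, MODIFIERS, resolver)
            for a in annotated:
                expected = brute_force_modifiers(
                    text, span, a.mention.span, MODIFIERS.entries, resolver
                )
                assert a.modifier_map() == expected

    def test_removing_a_variant_never_adds_mentions_here(self):
        # non-overlapping lexicon: dropping entries can only shrink the output
        rng = random.Random(44)
        entries = [LexiconEntry(w, w) for w in ("ica", "occlusion", "stenosis", "patent")]
        full = compile_lexicon(entries)
        reduced = compile_lexicon(entries[1:])
        for _ in range(100):
            text = " ".join(rng.choice(self.VOCAB) for _ in range(rng.randint(1, 8)))
            span = (0, len(text))
            full_set = {(m.span, m.category) for m in match_targets(text, span, full)}
            reduced_set = {(m.span, m.category) for m in match_targets(text, span, reduced)}
            assert reduced_set <= full_set


def test_resolver_maps_value_tokens_to_classes(registry):
    resolve = default_category_resolver(registry)
    assert resolve("Definite_Negated_Existence") == "Certainty"
    assert resolve("Mild_Severity") == "Severity"
    assert resolve("Left_Body_Side") == "Body Side"
    assert resolve("80_To_100_Mg_Dosage") == "Dosage"
    assert resolve("Something_Unknown") == "Something_Unknown"


def test_knowtator_writer_produces_wellformed_xml(tmp_path):
    from xml.etree import ElementTree as ET

    text = "no occlusion"
    mentions = match_targets(text, (0, len(text)), TARGETS)
    annotated = apply_modifiers(text, (0, len(text)), mentions, MODIFIERS)
    path = tmp_path / "doc.knowtator.xml"
    write_knowtator_xml("doc", annotated, path)
    root = ET.parse(path).getroot()
    assert root.tag == "annotations"
    assert root.find(".//classMention/mentionClass").get("id") == "occlusion"
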