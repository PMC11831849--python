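"""BIO projection, corpus construction, and the correction workflow."""

import pytest

from deidkit.core import PHICategory, Span
from deidkit.errors import CorpusError, CorrectionError, DeidError
from deidkit.pseudo_label import (
    CorrectionList,
    Tier,
    apply_corrections,
    build_corpus,
    corrections_from_gold,
    count_phi_words,
    entity_runs,
    is_bio_valid,
    label_note,
    label_note_gold,
    project_to_bio,
)
from deidkit.rules import RuleMatch, apply_rules
from deidkit.synth import SynthConfig, generate_corpus
from deidkit.tokenize import tokenize


class TestProjectToBio:
    def test_patient_name_example(self, ruleset, make_note):
        note = make_note("환자이름: 홍길동")
        tokens = tokenize(note.text)
        tags = [t.tag for t in project_to_bio(tokens, apply_rules(note, ruleset))]
        assert tags == ["O", "O", "B-PER"]

    def test_no_matches_all_o(self, make_note):
        note = make_note("특이 소견 없음.")
        labeled = project_to_bio(tokenize(note.text), [])
        assert all(t.tag == "O" for t in labeled)

    def test_multi_token_match_gets_b_then_i(self, ruleset, make_note):
        note = make_note("2019-02-04 촬영")
        tags = [t.tag for t in label_note(note, ruleset).tokens]
        assert tags == ["B-DAT", "I-DAT", "I-DAT", "I-DAT", "I-DAT", "O"]

    def test_staff_and_patient_both_map_to_per(self, ruleset, make_note):
        note = make_note("판독의: 이영희\n환자이름: 김민준")
        tags = [t.tag for t in label_note(note, ruleset).tokens]
        assert tags.count("B-PER") == 2

    def test_overlapping_matches_rejected(self, make_note):
        note = make_note("abcdef")
        ms = [
            RuleMatch("a", Span(0, 4), PHICategory.DAT),
            RuleMatch("b", Span(2, 6), PHICategory.PER),
        ]
        with pytest.raises(DeidError):
            project_to_bio(tokenize(note.text), ms)

    def test_round_trip_hull_recovery(self, ruleset, small_corpus):
        """Recovering spans from BIO runs reproduces the token-aligned hull
        of each rule match."""
        for an in small_corpus:
            matches = apply_rules(an.note, ruleset)
            tokens = tokenize(an.note.text)
            labeled = project_to_bio(tokens, matches)
            runs = entity_runs(labeled)
            assert len(runs) == len(matches)
            for (cat, hull), match in zip(runs, matches):
                assert cat == match.category.value
                assert hull.overlaps(match.span)
                covered = [sp for _, sp in tokens if sp.overlaps(match.span)]
                assert hull.start == covered[0].start
                assert hull.end == covered[-1].end

    def test_bio_validity_everywhere(self, ruleset, mixed_corpus):
        for an in mixed_corpus:
            assert is_bio_valid([t.tag for t in label_note(an.note, ruleset).tokens])
            assert is_bio_valid([t.tag for t in label_note_gold(an).tokens])


@pytest.fixture(scope="module")
def pool():
    return generate_corpus(SynthConfig(seed=77, n_notes=100, phi_note_fraction=0.4))


class TestBuildCorpus:

    def test_every_note_has_phi(self, pool, ruleset):
        corpus = build_corpus([an.note for an in pool], ruleset, "small", 10, seed=7)
        assert len(corpus) == 10
        for tn in corpus.notes:
            assert any(t.tag != "O" for t in tn.tokens)

    def test_same_seed_same_corpus(self, pool, ruleset):
        notes = [an.note for an in pool]
        a = build_corpus(notes, ruleset, "small", 10, seed=7)
        b = build_corpus(notes, ruleset, "small", 10, seed=7)
        assert [tn.note.note_id for tn in a.notes] == [tn.note.note_id for tn in b.notes]
        assert [[t.tag for t in tn.tokens] for tn in a.notes] == [
            [t.tag for t in tn.tokens] for tn in b.notes
        ]

    def test_different_seed_different_sample(self, pool, ruleset):
        notes = [an.note for an in pool]
        a = build_corpus(notes, ruleset, "small", 10, seed=7)
        b = build_corpus(notes, ruleset, "small", 10, seed=8)
        assert [tn.note.note_id for tn in a.notes] != [tn.note.note_id for tn in b.notes]

    def test_insufficient_phi_notes_errors_with_counts(self, pool, ruleset):
        with pytest.raises(CorpusError, match=r"\d+"):
            build_corpus([an.note for an in pool], ruleset, "small", 99, seed=7)

    def test_phi_word_counts_equal_b_runs(self, pool, ruleset):
        corpus = build_corpus([an.note for an in pool], ruleset, "small", 20, seed=3)
        assert corpus.phi_word_counts == count_phi_words(corpus.notes)
        total_b = sum(
            sum(1 for t in tn.tokens if t.tag.startswith("B-")) for tn in corpus.notes
        )
        assert sum(corpus.phi_word_counts.values()) == total_b


class TestCorrections:
    @pytest.fixture()
    def trap_corpus(self, ruleset):
        pool = generate_corpus(
            SynthConfig(seed=88, n_notes=120, phi_note_fraction=1.0, homonym_trap_rate=0.5)
        )
        corpus = build_corpus([an.note for an in pool], ruleset, "large1", 100, seed=5)
        gold = {an.note.note_id: an.annotations for an in pool}
        return corpus, gold

    def test_empty_corrections_change_only_tier(self, trap_corpus):
        corpus, _ = trap_corpus
        out = apply_corrections(corpus, CorrectionList())
        assert out.tier is Tier.LARGE2
        assert [[t.tag for t in tn.tokens] for tn in out.notes] == [
            [t.tag for t in tn.tokens] for tn in corpus.notes
        ]

    def test_flagged_false_positives_become_o(self, trap_corpus, ruleset):
        corpus, gold = trap_corpus
        corrections = corrections_from_gold(corpus, gold)
        assert corrections.removals, "trap-laden corpus should yield removals"
        out = apply_corrections(corpus, corrections)
        # after correction no entity run lies outside gold
        for tn in out.notes:
            gold_spans = [a.span for a in gold[tn.note.note_id]]
            for _, hull in entity_runs(tn.tokens):
                assert any(hull.overlaps(g) for g in gold_spans)

    def test_note_losing_last_annotation_is_dropped(self, ruleset, make_note):
        note = make_note("orientation을 고려해 볼 때")  # single (false-positive) match
        corpus = build_corpus([note], ruleset, "custom", 1, seed=0)
        corrections = corrections_from_gold(corpus, {note.note_id: []})
        out = apply_corrections(corpus, corrections)
        assert len(out.notes) == 0

    def test_dangling_removal_rejected(self, trap_corpus):
        corpus, _ = trap_corpus
        bad = CorrectionList(removals=[("no-such-note", Span(0, 3))])
        with pytest.raises(CorrectionError):
            apply_corrections(corpus, bad)

    def test_additions_append_gold_notes(self, trap_corpus):
        corpus, _ = trap_corpus
        additions = generate_corpus(
            SynthConfig(seed=99, n_notes=5, phi_note_fraction=1.0, department_mix=1.0)
        )
        out = apply_corrections(corpus, CorrectionList(additions=additions))
        assert len(out.notes) == len(corpus.notes) + 5
        depts = {tn.note.department.value for tn in out.notes}
        assert "other" in depts
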