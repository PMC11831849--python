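"""Rule engine: structure, per-family behavior (including documented
over-triggers), overlap resolution, masking, and the brute-force oracle."""

import pytest

from deidkit.core import PHICategory, PersonRole, Span
from deidkit.errors import DeidError, RuleConfigError
from deidkit.rules import (
    RuleMatch,
    apply_rules,
    compile_ruleset,
    mask_text,
    match_dates,
    match_num_etc,
    match_org_loc,
    match_person,
    resolve_overlaps,
    run_rule,
)
from deidkit.synth import SynthConfig, generate_corpus


def spans_of(matches, text):
    return [(m.span.slice(text), m.category.value) for m in matches]


class TestRuleSetStructure:
    def test_total_of_51_rules(self, ruleset):
        assert len(ruleset) == 51

    def test_per_category_counts(self, ruleset):
        assert ruleset.category_counts == {
            "DAT": 18,
            "PER.staff": 8,
            "PER.patient": 3,
            "ORG": 13,
            "LOC": 1,
            "NUM": 4,
            "ETC": 4,
        }

    def test_compilation_deterministic(self):
        a = compile_ruleset()
        b = compile_ruleset()
        assert [r.pattern for r in a.rules] == [r.pattern for r in b.rules]

    def test_malformed_pattern_names_rule(self):
        cfg = {"rules": [{"id": "bad_rule", "category": "DAT", "pattern": "(?P<phi>["}]}
        with pytest.raises(RuleConfigError, match="bad_rule"):
            compile_ruleset(cfg)

    def test_missing_phi_group_rejected(self):
        cfg = {"rules": [{"id": "no_group", "category": "DAT", "pattern": "abc"}]}
        with pytest.raises(RuleConfigError, match="no_group"):
            compile_ruleset(cfg)

    def test_count_mismatch_rejected(self):
        cfg = {
            "rules": [{"id": "r1", "category": "DAT", "pattern": "(?P<phi>x)"}],
            "expected_counts": {"DAT": 2},
        }
        with pytest.raises(RuleConfigError, match="count mismatch"):
            compile_ruleset(cfg)


class TestDates:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("specific dates such as 2019-02-04", "2019-02-04"),
            ("2020년 3월 7일 촬영", "2020년 3월 7일"),
            ("촬영일 2019.2.4 참조", "2019.2.4"),
            ("촬영일 2019. 2. 4 참조", "2019. 2. 4"),
            ("exam on 2019/02/04 noted", "2019/02/04"),
            ("접수 20190204 기준", "20190204"),
            ("이전 검사 '19.2.4 참조", "'19.2.4"),
            ("이전 검사 '19-2-4 참조", "'19-2-4"),
            ("study of Feb 4, 2019 reviewed", "Feb 4, 2019"),
            ("study of February 2019 reviewed", "February 2019"),
            ("2019년 11월 시행", "2019년 11월"),
            ("3월 7일 재촬영", "3월 7일"),
            ("2019년 내원", "2019년"),
            ("f/u 3/15 예정", "3/15"),
        ],
    )
    def test_covered_notations(self, ruleset, make_note, text, expected):
        matches = match_dates(make_note(text), ruleset)
        assert [m.span.slice(text) for m in matches] == [expected]
        assert all(m.category is PHICategory.DAT for m in matches)

    @pytest.mark.parametrize(
        "text",
        [
            "1.2-1.7 cm sized nodule",  # numeric range without a year
            "bare 2019 without context",
            "measurement 7.3.2 protocol",
            "accession 5482-3310 today",
        ],
    )
    def test_ambiguous_numerics_not_matched(self, ruleset, make_note, text):
        assert match_dates(make_note(text), ruleset) == []


class TestPerson:
    def test_patient_identifier(self, ruleset, make_note):
        text = "환자이름: 홍길동"
        matches = match_person(make_note(text), ruleset)
        assert spans_of(matches, text) == [("홍길동", "PER")]
        assert matches[0].subcategory is PersonRole.PATIENT

    def test_over_trigger_on_sanggi(self, ruleset, make_note):
        """The 확인함 and by rules fire together: 상기 is tagged although it
        should be O — a documented over-trigger kept by design."""
        text = "상기확인함 by 홍길동"
        matches = match_person(make_note(text), ruleset)
        assert spans_of(matches, text) == [("상기", "PER"), ("홍길동", "PER")]
        assert all(m.subcategory is PersonRole.STAFF for m in matches)

    def test_slash_initials(self, ruleset, make_note):
        text = " /jmk/"
        matches = match_person(make_note(text), ruleset)
        assert spans_of(matches, text) == [("jmk", "PER")]

    def test_multi_slash_initials(self, ruleset, make_note):
        text = "///skd/"
        matches = match_person(make_note(text), ruleset)
        assert [m.span.slice(text) for m in matches] == ["skd"]

    def test_identifier_words_not_masked(self, ruleset, make_note):
        text = "판독의: 이영희"
        n = make_note(text)
        masked = mask_text(n, apply_rules(n, ruleset))
        assert masked == "판독의: [PER]"


class TestOrgLoc:
    def test_hospital_alias(self, ruleset, make_note):
        text = "고려대병원 에서 전원"
        matches = match_org_loc(make_note(text), ruleset)
        assert spans_of(matches, text) == [("고려대병원", "ORG")]

    def test_homonym_false_positive_koryo(self, ruleset, make_note):
        """고려 (considering) is tagged ORG — a documented homonym trap."""
        text = "orientation을 고려해 볼 때"
        matches = match_org_loc(make_note(text), ruleset)
        assert spans_of(matches, text) == [("고려", "ORG")]

    def test_homonym_false_positive_median(self, ruleset, make_note):
        text = "측정된 중앙값 범위"
        matches = match_org_loc(make_note(text), ruleset)
        assert [m.span.slice(text) for m in matches] == ["중앙"]

    def test_cmc_fires_regardless_of_context(self, ruleset, make_note):
        for text in ["CMC", "Rt. 1st CMC joint", "transfer to CMC"]:
            matches = match_org_loc(make_note(text), ruleset)
            assert [m.span.slice(text) for m in matches] == ["CMC"], text

    def test_standalone_region_is_loc(self, ruleset, make_note):
        text = "대구 local 검사"
        matches = match_org_loc(make_note(text), ruleset)
        assert spans_of(matches, text) == [("대구", "LOC")]

    def test_city_plus_hospital_resolves_to_org(self, ruleset, make_note):
        text = "분당제생병원 영상"
        matches = match_org_loc(make_note(text), ruleset)
        assert spans_of(matches, text) == [("분당제생병원", "ORG")]

    def test_clinic_suffix(self, ruleset, make_note):
        text = "서울내과의원 소견서 지참"
        matches = match_org_loc(make_note(text), ruleset)
        assert spans_of(matches, text) == [("서울내과의원", "ORG")]


class TestNumEtc:
    def test_identifier_anchored_number(self, ruleset, make_note):
        text = "Tel. 1234"
        matches = match_num_etc(make_note(text), ruleset)
        assert spans_of(matches, text) == [("1234", "NUM")]

    def test_bare_four_digits_not_matched(self, ruleset, make_note):
        assert match_num_etc(make_note("내선은 2019 입니다"), ruleset) == []

    def test_extension_vocabulary(self, make_note):
        cfg = compile_ruleset()
        import copy

        from deidkit.rules import load_rule_config

        raw = load_rule_config()
        raw = copy.deepcopy(raw)
        raw["vocab"]["extension"] = ["7714"]
        rs = compile_ruleset(raw)
        text = "연결 7714 부탁"
        matches = match_num_etc(make_note(text), rs)
        assert spans_of(matches, text) == [("7714", "NUM")]
        # same text under the default (empty) extension vocabulary: no match
        assert match_num_etc(make_note(text), cfg) == []

    def test_age_and_sex(self, ruleset, make_note):
        text = "45세 남자"
        matches = match_num_etc(make_note(text), ruleset)
        assert spans_of(matches, text) == [("45세", "ETC"), ("남자", "ETC")]

    def test_phone_number(self, ruleset, make_note):
        text = "전화번호: 031-456-7890"
        matches = match_num_etc(make_note(text), ruleset)
        assert spans_of(matches, text) == [("031-456-7890", "NUM")]


class TestResolveOverlaps:
    def test_empty(self):
        assert resolve_overlaps([]) == []

    def test_longer_span_wins(self):
        a = RuleMatch("r_org", Span(0, 10), PHICategory.ORG, priority=1)
        b = RuleMatch("r_loc", Span(0, 5), PHICategory.LOC, priority=2)
        assert resolve_overlaps([a, b]) == [a]

    def test_equal_span_org_beats_loc(self):
        loc = RuleMatch("r_loc", Span(3, 7), PHICategory.LOC, priority=1)
        org = RuleMatch("r_org", Span(3, 7), PHICategory.ORG, priority=2)
        assert resolve_overlaps([loc, org]) == [org]

    def test_full_category_precedence_chain(self):
        order = [
            PHICategory.ORG,
            PHICategory.LOC,
            PHICategory.DAT,
            PHICategory.PER,
            PHICategory.NUM,
            PHICategory.ETC,
        ]
        for hi, lo in zip(order, order[1:]):
            a = RuleMatch("a", Span(0, 4), hi, priority=9)
            b = RuleMatch("b", Span(0, 4), lo, priority=1)
            assert resolve_overlaps([a, b]) == [a], (hi, lo)

    def test_result_sorted_and_disjoint(self):
        ms = [
            RuleMatch("a", Span(5, 9), PHICategory.DAT),
            RuleMatch("b", Span(0, 4), PHICategory.PER),
            RuleMatch("c", Span(3, 6), PHICategory.NUM),
        ]
        out = resolve_overlaps(ms)
        starts = [m.span.start for m in out]
        assert starts == sorted(starts)
        for x, y in zip(out, out[1:]):
            assert not x.span.overlaps(y.span)


class TestMasking:
    def test_category_placeholder(self, ruleset, make_note):
        n = make_note("2019-02-04 촬영")
        assert mask_text(n, apply_rules(n, ruleset)) == "[DAT] 촬영"

    def test_no_matches_identity(self, ruleset, make_note):
        n = make_note("특이 소견 없음.")
        assert mask_text(n, []) == n.text

    def test_overlapping_spans_rejected(self, make_note):
        n = make_note("abcdefgh")
        ms = [
            RuleMatch("a", Span(0, 4), PHICategory.DAT),
            RuleMatch("b", Span(2, 6), PHICategory.PER),
        ]
        with pytest.raises(DeidError):
            mask_text(n, ms)

    def test_masking_is_fixed_point(self, ruleset, small_corpus):
        """Masking already-masked text changes nothing: placeholders are
        not re-masked and no residual context re-fires a rule."""
        from deidkit.core import ClinicalNote

        for an in small_corpus:
            matches = apply_rules(an.note, ruleset)
            masked = mask_text(an.note, matches)
            n2 = ClinicalNote(an.note.note_id, an.note.department, masked)
            assert mask_text(n2, apply_rules(n2, ruleset)) == masked

    def test_masked_output_drops_every_matched_character(self, ruleset, small_corpus):
        for an in small_corpus:
            matches = apply_rules(an.note, ruleset)
            masked = mask_text(an.note, matches)
            # reconstruct the unmasked remainder and compare piecewise
            pos, pieces = 0, []
            for m in matches:
                pieces.append(an.note.text[pos : m.span.start])
                pos = m.span.end
            pieces.append(an.note.text[pos:])
            expected = "".join(
                p + f"[{m.category.value}]" for p, m in zip(pieces, matches)
            ) + pieces[-1]
            assert masked == expected


class TestApplyRulesOracle:
    def test_empty_note_no_matches(self, ruleset, make_note):
        assert apply_rules(make_note("x"), ruleset) == []

    def test_composed_example(self, ruleset, make_note):
        text = "2019-02-04 촬영\n환자이름: 홍길동"
        matches = apply_rules(make_note(text), ruleset)
        assert spans_of(matches, text) == [("2019-02-04", "DAT"), ("홍길동", "PER")]

    def test_matches_brute_force_oracle(self, ruleset, mixed_corpus):
        """apply_rules == run every rule independently, then resolve."""
        for an in mixed_corpus:
            brute = []
            for rule in ruleset.rules:
                brute.extend(run_rule(rule, an.note.text))
            assert apply_rules(an.note, ruleset) == resolve_overlaps(brute)

    def test_deterministic_across_runs(self, ruleset):
        corpus = generate_corpus(SynthConfig(seed=11, n_notes=50, phi_note_fraction=1.0))
        first = [apply_rules(an.note, ruleset) for an in corpus]
        second = [apply_rules(an.note, compile_ruleset()) for an in corpus]
        assert first == second
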